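import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatialtx import spatial_cna, synth
from spatialtx.errors import ValidationError
from spatialtx.io_model import GeneCoordinateTable, ProbeRegionSet
from spatialtx.spatial_cna import (
    ProbeScoreMatrix,
    call_cells,
    compute_probe_scores,
    map_genes_to_probes,
    validate_probes,
)

from conftest import make_dataset


def gene_table(rows):
    return GeneCoordinateTable(
        table=pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    )


def probe_set(rows):
    return ProbeRegionSet(
        table=pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end", "event"])
    )


class TestMapGenesToProbes:
    def test_full_containment(self):
        genes = gene_table([("CCND1", "chr11", 69_641_156, 69_654_474)])
        probes = probe_set([("p11q13", "chr11", 69_000_000, 70_000_000, "gain")])
        mapped = map_genes_to_probes(genes, probes)
        assert mapped.member_genes["p11q13"] == ["CCND1"]

    def test_single_base_overlap(self):
        genes = gene_table([("GA", "chr1", 100, 200)])
        probes = probe_set([("p", "chr1", 199, 300, "gain")])
        assert map_genes_to_probes(genes, probes).member_genes["p"] == ["GA"]

    def test_half_open_no_touch(self):
        genes = gene_table([("GA", "chr1", 100, 200)])
        probes = probe_set([("p", "chr1", 200, 300, "gain")])
        assert map_genes_to_probes(genes, probes).member_genes["p"] == []

    def test_chromosome_mismatch(self):
        genes = gene_table([("GA", "chr1", 100, 200)])
        probes = probe_set([("p", "chr2", 100, 200, "gain")])
        assert map_genes_to_probes(genes, probes).member_genes["p"] == []


class TestComputeProbeScores:
    def _mapped_probes(self, event="gain"):
        genes = gene_table([("G0", "chr1", 0, 10), ("G1", "chr1", 20, 30)])
        probes = probe_set([("p", "chr1", 0, 30, event)])
        return map_genes_to_probes(genes, probes)

    def test_oracle_equivalence_hand_computed(self):
        # <=10 cells x <=6 genes; independent mean/SD arithmetic to 1e-12
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 20, size=(8, 2))
        ds = make_dataset(counts, cell_type=["ref"] * 5 + ["cand"] * 3)
        scores = compute_probe_scores(ds, self._mapped_probes(), {"ref"})

        totals = counts.sum(axis=1)
        target = np.median(totals)
        norm = np.log1p(counts / totals[:, None] * target)
        raw = norm.mean(axis=1)
        mu, sd = raw[:5].mean(), raw[:5].std(ddof=1)
        expected = (raw - mu) / sd
        np.testing.assert_allclose(scores.scores[:, 0], expected, atol=1e-12)

    def test_reference_mean_cell_scores_zero(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 30, size=(10, 2))
        ds = make_dataset(counts, cell_type=["ref"] * 10)
        scores = compute_probe_scores(ds, self._mapped_probes(), {"ref"})
        # reference population z-scores average to ~0 by construction
        assert scores.scores[:, 0].mean() == pytest.approx(0.0, abs=1e-12)

    def test_loss_probe_inverted(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 30, size=(10, 2))
        ds = make_dataset(counts, cell_type=["ref"] * 10)
        gain = compute_probe_scores(ds, self._mapped_probes("gain"), {"ref"})
        loss = compute_probe_scores(ds, self._mapped_probes("loss"), {"ref"})
        np.testing.assert_allclose(loss.scores, -gain.scores, atol=1e-12)

    def test_empty_probe_unscoreable(self):
        genes = gene_table([("G0", "chr1", 0, 10), ("G1", "chr1", 20, 30)])
        probes = probe_set(
            [("ok", "chr1", 0, 30, "gain"), ("empty", "chr9", 0, 30, "gain")]
        )
        mapped = map_genes_to_probes(genes, probes)
        rng = np.random.default_rng(4)
        ds = make_dataset(rng.integers(1, 30, size=(10, 2)), cell_type=["ref"] * 10)
        scores = compute_probe_scores(ds, mapped, {"ref"})
        assert scores.unscoreable == ["empty"]
        assert list(scores.probe_ids) == ["ok"]


def _score_matrix(cand, ref, event="gain"):
    """Wrap candidate/reference score vectors in a ProbeScoreMatrix."""
    scores = np.concatenate([cand, ref])[:, None]
    cells = np.array(
        [f"cand{i}" for i in range(len(cand))] + [f"ref{i}" for i in range(len(ref))],
        dtype=object,
    )
    return ProbeScoreMatrix(
        scores=scores,
        probe_ids=np.array(["p"], dtype=object),
        events=np.array([event], dtype=object),
        cell_ids=cells,
        reference_cell_ids=cells[len(cand):],
        reference_mean=np.zeros(1),
        reference_sd=np.ones(1),
    )


class TestValidateProbes:
    def test_null_not_validated(self):
        rng = np.random.default_rng(0)
        sample = rng.normal(size=1000)
        sm = _score_matrix(sample[:500], sample[500:])
        val = validate_probes(sm, {f"cand{i}" for i in range(500)})
        row = val.table.iloc[0]
        assert not row["validated"]
        assert abs(row["effect_size"]) < 0.1

    def test_shifted_validates(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=500)
        cand = rng.normal(loc=1.0, size=500)
        sm = _score_matrix(cand, ref)
        val = validate_probes(sm, {f"cand{i}" for i in range(500)})
        row = val.table.iloc[0]
        assert row["validated"]
        assert row["p_adjusted"] < 0.05
        assert row["effect_size"] > 0.3
        assert row["direction"] > 0

    def test_wrong_direction_gated(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=500)
        cand = rng.normal(loc=-1.0, size=500)  # under-expressed vs gain probe
        sm = _score_matrix(cand, ref)
        val = validate_probes(sm, {f"cand{i}" for i in range(500)})
        row = val.table.iloc[0]
        assert row["direction"] < 0
        assert not row["validated"]
        assert row["p_adjusted"] < 0.05  # significance alone must not validate

    def test_p_matches_scipy(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=80)
        cand = rng.normal(loc=0.4, size=60)
        sm = _score_matrix(cand, ref)
        val = validate_probes(sm, {f"cand{i}" for i in range(60)})
        expected = stats.mannwhitneyu(
            cand, ref, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        assert val.table.iloc[0]["p_raw"] == pytest.approx(expected, rel=1e-9)

    def test_bonferroni_monotone_in_probe_count(self):
        rng = np.random.default_rng(4)
        cand = rng.normal(0.5, size=100)
        ref = rng.normal(size=100)

        def adj_p(n_probes):
            scores = np.tile(np.concatenate([cand, ref])[:, None], (1, n_probes))
            cells = np.array(
                [f"cand{i}" for i in range(100)] + [f"ref{i}" for i in range(100)],
                dtype=object,
            )
            sm = ProbeScoreMatrix(
                scores=scores,
                probe_ids=np.array([f"p{j}" for j in range(n_probes)], dtype=object),
                events=np.array(["gain"] * n_probes, dtype=object),
                cell_ids=cells,
                reference_cell_ids=cells[100:],
                reference_mean=np.zeros(n_probes),
                reference_sd=np.ones(n_probes),
            )
            val = validate_probes(sm, {f"cand{i}" for i in range(100)})
            return val.table["p_adjusted"].iloc[0]

        assert adj_p(1) <= adj_p(3) <= adj_p(10)

    def test_overlapping_sets_rejected(self):
        sm = _score_matrix(np.zeros(3), np.ones(3))
        with pytest.raises(ValidationError, match="disjoint"):
            validate_probes(sm, {"cand0", "ref0"})


class TestCallCells:
    def _validation(self, validated=True):
        return spatial_cna.ProbeValidation(
            table=pd.DataFrame(
                [{"probe_id": "p", "event": "gain", "p_raw": 0.0, "p_adjusted": 0.0,
                  "effect_size": 1.0, "rank_biserial_r": 1.0, "cohens_d": 2.0,
                  "direction": 1.0, "validated": validated}]
            )
        )

    def test_single_probe_burden_is_column(self):
        rng = np.random.default_rng(0)
        sm = _score_matrix(rng.normal(5, 1, 50), rng.normal(0, 1, 50))
        res = call_cells(sm, self._validation(), seed=0)
        np.testing.assert_array_equal(res.burden, sm.scores[:, 0])

    def test_well_separated_mixture_accuracy(self):
        rng = np.random.default_rng(5)
        high = rng.normal(10, 1, 500)
        low = rng.normal(0, 1, 500)
        sm = _score_matrix(high, low)
        res = call_cells(sm, self._validation(), seed=0)
        truth = np.array(["cna_altered"] * 500 + ["diploid"] * 500)
        assert (res.label == truth).mean() >= 0.99
        assert res.status == "fit"
        # altered component has the larger mean
        assert res.posterior_altered[:500].mean() > 0.95

    def test_zero_validated_all_diploid(self):
        rng = np.random.default_rng(6)
        sm = _score_matrix(rng.normal(5, 1, 20), rng.normal(0, 1, 20))
        res = call_cells(sm, self._validation(validated=False), seed=0)
        assert res.status == "no_validated_probes"
        assert set(res.label) == {"diploid"}
        assert np.all(res.burden == 0)

    def test_degenerate_identical_burdens(self):
        sm = _score_matrix(np.full(10, 2.0), np.full(10, 2.0))
        res = call_cells(sm, self._validation(), seed=0)
        assert res.status == "degenerate"
        assert set(res.label) == {"diploid"}


class TestPipelineOnSynthetic:
    def test_loss_probe_positive_after_inversion(self):
        cfg = synth.cna_benchmark_config(fold_change=0.5, event="loss", seed=2)
        ds, gt = synth.simulate_dataset(cfg)
        scores, val, calls = spatial_cna.run_cna_pipeline(
            ds, synth.probe_regions(cfg), synth.gene_table(cfg),
            reference_types=["Fibroblast", "Immune"],
            candidate_types=["Malignant"], seed=0,
        )
        mal = gt["is_malignant"].to_numpy()
        assert scores.scores[mal, 0].mean() > 0
        assert val.table.iloc[0]["validated"]

    def test_type_one_control_small(self):
        # quick 15-replicate version; the full 100-replicate run is in acceptance
        hits = 0
        for seed in range(15):
            cfg = synth.cna_benchmark_config(
                n_malignant=100, n_diploid=100, fold_change=1.0, seed=100 + seed
            )
            ds, _ = synth.simulate_dataset(cfg)
            _, val, _ = spatial_cna.run_cna_pipeline(
                ds, synth.probe_regions(cfg), synth.gene_table(cfg),
                reference_types=["Fibroblast", "Immune"],
                candidate_types=["Malignant"], seed=0,
            )
            hits += bool(val.table["validated"].any())
        assert hits <= 2
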