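"""QC filter, windowed CNV inference, burden and the dual-criterion call."""

import numpy as np
import pandas as pd
import pytest

from aegmap._utils import lognorm_cp10k
from aegmap.malignancy import (
    CnvProfile,
    annotate_minor_types,
    call_malignant,
    cnv_burden,
    infer_cnv_profile,
    qc_filter,
)
from aegmap.signatures import SignatureSet

from conftest import small_config


def _counts_with_mito(mito_fracs, total=10_000, n_other=30):
    """One cell per requested mito fraction, fixed total counts."""
    genes = [f"MT-G{i}" for i in range(3)] + [f"G{i}" for i in range(n_other)]
    rows = []
    for f in mito_fracs:
        mito = total * f / 3
        other = total * (1 - f) / n_other
        rows.append([mito] * 3 + [other] * n_other)
    return pd.DataFrame(rows, columns=genes, index=[f"c{i}" for i in range(len(rows))])


class TestQcFilter:
    def test_mito_boundary_inclusive(self):
        counts = _counts_with_mito([0.21, 0.20, 0.05])
        kept, report = qc_filter(counts, max_mito=0.20, min_genes=10)
        assert list(kept.index) == ["c1", "c2"]  # 0.20 kept (<=), 0.21 removed
        assert report.n_removed_mito == 1

    def test_detected_gene_floor(self):
        counts = _counts_with_mito([0.05, 0.05], n_other=30)
        counts.iloc[1, 10:] = 0  # second cell detects only 7 non-mito genes
        kept, report = qc_filter(counts, max_mito=0.5, min_genes=10)
        assert list(kept.index) == ["c0"]
        assert report.n_removed_genes == 1

    def test_planted_failures_counted(self, small_scrna):
        counts, ann, _ = small_scrna
        bad = counts.index[:40]
        rigged = counts.copy()
        mt = [g for g in counts.columns if g.startswith("MT-")]
        # push 40 cells to ~50% mito
        fill = (rigged.loc[bad].sum(axis=1) / len(mt)).astype(rigged.dtypes.iloc[0])
        for g in mt:
            rigged.loc[bad, g] = fill
        kept, report = qc_filter(rigged, ann, max_mito=0.20, min_genes=0)
        assert report.n_removed_mito == 40
        assert not kept.index.isin(bad).any()

    def test_no_mito_genes_warns_and_skips(self):
        counts = pd.DataFrame([[5, 5]], columns=["G1", "G2"], index=["c0"])
        with pytest.warns(UserWarning, match="mito"):
            kept, _ = qc_filter(counts, max_mito=0.0, min_genes=1)
        assert len(kept) == 1


def _toy_annotation(n_genes, genes_per_chrom=20):
    chroms = [f"chr{i // genes_per_chrom + 1}" for i in range(n_genes)]
    return pd.DataFrame(
        {"chrom": chroms, "start": [1000 * (i % genes_per_chrom) for i in range(n_genes)]},
        index=pd.Index([f"G{i:03d}" for i in range(n_genes)], name="gene_id"),
    )


class TestCnvProfile:
    def test_cells_equal_to_reference_give_zero(self, rng):
        ann = _toy_annotation(60)
        base = rng.lognormal(size=60)
        counts = pd.DataFrame(
            np.tile(base, (8, 1)), columns=ann.index,
            index=[f"c{i}" for i in range(8)],
        )
        prof = infer_cnv_profile(counts, ann, reference_cells=counts.index[:4], k=5)
        np.testing.assert_allclose(prof.values.to_numpy(), 0.0, atol=1e-12)

    def test_window_one_reproduces_centered_clamped(self, rng):
        ann = _toy_annotation(60)
        counts = pd.DataFrame(
            rng.poisson(20.0, size=(10, 60)).astype(float), columns=ann.index,
            index=[f"c{i}" for i in range(10)],
        )
        ref = counts.index[:5]
        prof = infer_cnv_profile(counts, ann, ref, k=1, clamp=3.0)
        ln = lognorm_cp10k(counts) / np.log(2.0)  # profile is in log2 units
        centered = ln - ln.loc[ref].mean(axis=0)
        centered = centered.clip(-3, 3)
        np.testing.assert_allclose(
            prof.values.to_numpy(),
            centered[prof.values.columns].to_numpy(),
            atol=1e-12,
        )

    def test_reference_mean_exactly_zero_before_smoothing(self, rng):
        ann = _toy_annotation(40)
        counts = pd.DataFrame(
            rng.poisson(15.0, size=(12, 40)).astype(float), columns=ann.index,
            index=[f"c{i}" for i in range(12)],
        )
        ref = counts.index[:6]
        prof = infer_cnv_profile(counts, ann, ref, k=1)
        np.testing.assert_allclose(
            prof.values.loc[ref].mean(axis=0).to_numpy(), 0.0, atol=1e-12
        )

    def test_planted_block_interior_magnitude(self, rng):
        # +1 log2 block of 500 genes (10% of a 5000-gene genome), window 101:
        # smoothed log2 ratio over the block interior lands in [0.5, 1.0]
        # for carrier cells and stays near 0 for reference-like cells
        n_genes, n_per_chrom = 5000, 500
        ann = _toy_annotation(n_genes, genes_per_chrom=n_per_chrom)
        base = rng.lognormal(0.5, 1.0, n_genes)
        block = np.zeros(n_genes)
        block[500:1000] = 1.0  # all of chr2
        n_ref = n_mal = 60
        counts = np.vstack(
            [
                rng.poisson(np.tile(base, (n_ref, 1))),
                rng.poisson(np.tile(base * 2.0**block, (n_mal, 1))),
            ]
        )
        idx = [f"r{i}" for i in range(n_ref)] + [f"m{i}" for i in range(n_mal)]
        df = pd.DataFrame(counts, index=idx, columns=ann.index)
        prof = infer_cnv_profile(df, ann, idx[:n_ref], k=101)
        interior = ann.index[700:800]
        mal_mean = prof.values.loc[idx[n_ref:], interior].to_numpy().mean()
        ref_mean = prof.values.loc[idx[:n_ref], interior].to_numpy().mean()
        assert 0.5 <= mal_mean <= 1.0
        assert abs(ref_mean) < 0.1

    def test_smoothing_never_crosses_chromosomes(self):
        # all of chr1 elevated in the query; chr2 must stay exactly zero
        ann = _toy_annotation(40)
        vals = pd.DataFrame(
            np.zeros((2, 40)), columns=ann.index, index=["ref", "q"]
        )
        vals.loc["q", ann.index[ann["chrom"] == "chr1"]] = 4.0
        prof = infer_cnv_profile(vals, ann, ["ref"], k=9, clamp=10.0, is_lognorm=True)
        chr1 = ann.index[ann["chrom"] == "chr1"]
        chr2 = ann.index[ann["chrom"] == "chr2"]
        np.testing.assert_allclose(prof.values.loc["q", chr1].to_numpy(), 4.0)
        np.testing.assert_allclose(prof.values.loc["q", chr2].to_numpy(), 0.0)

    def test_empty_reference_raises(self, rng):
        ann = _toy_annotation(40)
        counts = pd.DataFrame(
            rng.poisson(10.0, size=(4, 40)).astype(float), columns=ann.index
        )
        with pytest.raises(ValueError, match="reference"):
            infer_cnv_profile(counts, ann, [])

    def test_even_window_rejected(self, rng):
        ann = _toy_annotation(40)
        counts = pd.DataFrame(
            rng.poisson(10.0, size=(4, 40)).astype(float), columns=ann.index
        )
        with pytest.raises(ValueError, match="odd"):
            infer_cnv_profile(counts, ann, counts.index[:2], k=4)


class TestBurdenAndCall:
    def test_burden_zero_and_constant(self):
        z = CnvProfile(
            values=pd.DataFrame(np.zeros((3, 5))), window=1, reference_cells=pd.Index([])
        )
        assert (cnv_burden(z) == 0).all()
        c = CnvProfile(
            values=pd.DataFrame(np.full((3, 5), 0.3)), window=1, reference_cells=pd.Index([])
        )
        np.testing.assert_allclose(cnv_burden(c).to_numpy(), 0.09, atol=1e-12)

    def test_burden_separates_planted_truth(self, small_scrna):
        counts, ann, truth = small_scrna
        ref = counts.index[truth.cell_type.isin(["Tcell", "Bcell"])]
        burden = cnv_burden(infer_cnv_profile(counts, ann, ref))
        mal = truth.is_malignant.to_numpy()
        # rank-sum AUC of malignant over normal
        ranks = burden.rank()
        n1, n0 = mal.sum(), (~mal).sum()
        auc = (ranks[mal].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert auc >= 0.95

    def test_and_logic(self):
        cnv = pd.Series([0.9, 0.9, 0.1, 0.1], index=list("abcd"))
        sig = pd.Series([0.9, 0.1, 0.9, 0.1], index=list("abcd"))
        call = call_malignant(cnv, sig, method="quantile:0.5")
        assert call.is_malignant.to_dict() == {"a": True, "b": False, "c": False, "d": False}

    def test_two_means_recovers_bimodal_threshold(self, rng):
        lo = rng.normal(0.1, 0.02, 300)
        hi = rng.normal(0.8, 0.05, 120)
        scores = pd.Series(np.concatenate([lo, hi]))
        call = call_malignant(scores, scores, method="kmeans2")
        assert 0.2 < call.cnv_threshold < 0.7
        truth = np.concatenate([np.zeros(300, bool), np.ones(120, bool)])
        got = call.is_malignant.to_numpy()
        tp = (got & truth).sum()
        f1 = 2 * tp / (2 * tp + (got & ~truth).sum() + (~got & truth).sum())
        assert f1 >= 0.95

    def test_degenerate_scores_raise_with_hint(self):
        flat = pd.Series(np.ones(10))
        with pytest.raises(ValueError, match="quantile"):
            call_malignant(flat, flat)

    def test_misaligned_scores_raise(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        b = pd.Series([1.0, 2.0], index=["x", "z"])
        with pytest.raises(ValueError, match="aligned"):
            call_malignant(a, b)


class TestMinorTypes:
    def _expr_for(self, sets, cluster_sizes, rng):
        genes = sorted({g for s in sets.values() for g in s.positive}) + [
            f"bg{i}" for i in range(20)
        ]
        rows, labels = [], []
        for name, n in cluster_sizes.items():
            for _ in range(n):
                row = rng.lognormal(0, 0.2, len(genes))
                for j, g in enumerate(genes):
                    if g in sets[name].positive:
                        row[j] *= 20
                rows.append(row)
                labels.append(name)
        idx = [f"c{i}" for i in range(len(rows))]
        return (
            pd.DataFrame(rows, index=idx, columns=genes),
            pd.Series(labels, index=idx),
        )

    def test_clusters_labeled_by_expressed_set(self, rng):
        sets = {
            "chief": SignatureSet(positive=["PGA3", "LIPF", "PGC", "PGA4", "CHIA"]),
            "pit": SignatureSet(positive=["MUC5AC", "TFF1", "GKN1", "GKN2", "MUC1"]),
        }
        expr, clusters = self._expr_for(sets, {"chief": 12, "pit": 15}, rng)
        labels = annotate_minor_types(expr, sets, clusters)
        assert labels["chief"] == "chief"
        assert labels["pit"] == "pit"

    def test_exact_tie_goes_alphabetical_with_warning(self):
        expr = pd.DataFrame(
            [[5.0, 5.0, 1.0]], index=["c0"], columns=["a1", "b1", "x"]
        )
        sets = {
            "beta": SignatureSet(positive=["b1"]),
            "alpha": SignatureSet(positive=["a1"]),
        }
        clusters = pd.Series(["k"], index=["c0"])
        with pytest.warns(UserWarning, match="tie"):
            labels = annotate_minor_types(expr, sets, clusters)
        assert labels["k"] == "alpha"

    def test_empty_cluster_raises(self, rng):
        sets = {"A": SignatureSet(positive=["a1"])}
        expr = pd.DataFrame([[1.0, 2.0]], index=["c0"], columns=["a1", "x"])
        clusters = pd.Series(["k1", "k2"], index=["c0", "missing_cell"])
        with pytest.raises(ValueError, match="empty cluster"):
            annotate_minor_types(expr, sets, clusters)
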