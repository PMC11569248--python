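"""In-silico mutagenesis scoring, hQTL munging, aggregation, concordance."""

import numpy as np
import pytest

from epitype.errors import ConfigError, EmptyJoinError, RefAlleleMismatchError
from epitype.model import CelltypeFeatures
from epitype.regions import DataConfig
from epitype.variants import (
    AggregatedMarginal,
    HqtlRecord,
    SnpEffectScore,
    Variant,
    aggregate_all,
    aggregate_marginal,
    export_and_concord,
    munge_hqtl,
    score_variant,
    window_placements,
)


def mkvar(pos=50_000, ref="A", alt="C", vid="rs1", chrom="chr1"):
    return Variant(chrom, pos, ref, alt, vid)


def mkrec(var, peak_chrom=None, start=0, end=100, beta=1.0, p=0.5):
    return HqtlRecord(var, peak_chrom or var.chrom, start, end, beta, p)


class TestVariant:
    def test_indels_rejected(self):
        with pytest.raises(ConfigError):
            Variant("chr1", 5, "AT", "A", "x")

    def test_ref_mismatch(self):
        v = mkvar(pos=3, ref="G")
        with pytest.raises(RefAlleleMismatchError):
            v.check_ref({"chr1": "AAAAAA"})


class TestWindowPlacements:
    def test_full_scale_offsets(self):
        cfg = DataConfig.paper_profile()
        v = mkvar(pos=2_000_000)
        starts = window_placements(v, cfg, chrom_len=10_000_000)
        centre = starts[0]
        assert sorted(s - centre for s in starts) == [-40_960, 0, 40_960]

    def test_toy_offsets(self, toy_dcfg):
        v = mkvar(pos=30_000)
        starts = window_placements(v, toy_dcfg, chrom_len=65_536)
        centre = starts[0]
        assert sorted(s - centre for s in starts) == [-1024, 0, 1024]

    def test_appended_windows_tile_without_gaps(self, toy_dcfg):
        cfg = toy_dcfg
        v = mkvar(pos=30_000)
        starts = window_placements(v, cfg, chrom_len=65_536)
        # prediction windows: centre full + outer margins of the slid ones
        centre_pred = (starts[0] + cfg.margin, starts[0] + cfg.margin + cfg.window_len)
        down = (starts[1] + cfg.margin + cfg.window_len - cfg.margin,
                starts[1] + cfg.margin + cfg.window_len)
        up = (starts[2] + cfg.margin, starts[2] + cfg.margin + cfg.margin)
        spans = sorted([up, centre_pred, down])
        assert spans[0][1] == spans[1][0] and spans[1][1] == spans[2][0]
        total = sum(e - s for s, e in spans)
        assert total == cfg.window_len + 2 * cfg.margin == cfg.input_len

    def test_edge_placements_dropped_with_warning(self, toy_dcfg):
        v = mkvar(pos=2_500)
        with pytest.warns(UserWarning):
            starts = window_placements(v, toy_dcfg, chrom_len=65_536)
        assert len(starts) < 3


class _LinearStubModel:
    """prediction[t, m] = sum over the bin's bases of W[m, base]; W is
    complement-symmetric so the score has a strand-independent closed form."""

    def __init__(self, cfg, weights):
        self.cfg = cfg
        self.W = weights  # (n_marks, 4), complement-symmetric

    def forward(self, onehot, local, glob, latent=None):
        from epitype.nn import Tensor

        oh = onehot.data[0].T  # (L, 4)
        cfg = self.cfg
        per_base = oh @ self.W.T  # (L, n_marks)
        bins = per_base.reshape(-1, cfg.data.bin, cfg.n_marks).sum(axis=1)
        crop = (cfg.latent_positions - cfg.n_bins) // 2
        out = bins[crop : crop + cfg.n_bins]
        return {"combined": Tensor(out[None])}


class TestScoreVariant:
    @pytest.fixture
    def stub(self, toy_mcfg):
        w = np.array([[0.3, 0.7, 0.7, 0.3],   # A=T, C=G: complement symmetric
                      [1.0, 0.2, 0.2, 1.0],
                      [0.5, 0.5, 0.5, 0.5]])
        return _LinearStubModel(toy_mcfg, w)

    @pytest.fixture
    def sequences(self):
        rng = np.random.default_rng(0)
        return {"chr1": "".join(rng.choice(list("ACGT"), size=65_536))}

    def _features(self, mcfg):
        return CelltypeFeatures(np.zeros(mcfg.local_len), np.zeros(mcfg.global_len))

    def test_alt_equals_ref_scores_zero(self, stub, sequences, toy_mcfg):
        pos = 30_000
        v = Variant("chr1", pos, sequences["chr1"][pos], sequences["chr1"][pos], "rs0")
        s = score_variant(stub, sequences, self._features(toy_mcfg), v,
                          ["m0", "m1", "m2"])
        assert all(val == 0.0 for val in s.scores.values())

    def test_24_forward_passes_at_default_settings(self, stub, sequences, toy_mcfg):
        pos = 30_000
        ref = sequences["chr1"][pos]
        alt = [b for b in "ACGT" if b != ref][0]
        s = score_variant(stub, sequences, self._features(toy_mcfg),
                          Variant("chr1", pos, ref, alt, "rs1"), ["m0", "m1", "m2"])
        assert s.n_passes == 24

    def test_linear_model_closed_form(self, stub, sequences, toy_mcfg):
        """For the linear stub, the appended-window score is exactly
        W[m, alt] − W[m, ref]: the variant's bin appears in exactly one
        appended piece per placement set."""
        pos = 30_000
        ref = sequences["chr1"][pos]
        alt = [b for b in "ACGT" if b != ref][0]
        v = Variant("chr1", pos, ref, alt, "rs1")
        s = score_variant(stub, sequences, self._features(toy_mcfg), v,
                          ["m0", "m1", "m2"])
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, mark in enumerate(["m0", "m1", "m2"]):
            expected = stub.W[j, idx[alt]] - stub.W[j, idx[ref]]
            assert s.scores[mark] == pytest.approx(expected, abs=1e-12)

    def test_antisymmetric_under_allele_swap(self, stub, sequences, toy_mcfg):
        pos = 30_000
        ref = sequences["chr1"][pos]
        alt = [b for b in "ACGT" if b != ref][0]
        fwd = score_variant(stub, sequences, self._features(toy_mcfg),
                            Variant("chr1", pos, ref, alt, "rs1"),
                            ["m0", "m1", "m2"])
        swapped_seq = {"chr1": sequences["chr1"][:pos] + alt
                       + sequences["chr1"][pos + 1:]}
        rev = score_variant(stub, swapped_seq, self._features(toy_mcfg),
                            Variant("chr1", pos, alt, ref, "rs1"),
                            ["m0", "m1", "m2"])
        for mark in fwd.scores:
            assert fwd.scores[mark] == pytest.approx(-rev.scores[mark], abs=1e-12)

    def test_ref_mismatch_raises(self, stub, sequences, toy_mcfg):
        pos = 30_000
        wrong = [b for b in "ACGT" if b != sequences["chr1"][pos]][0]
        with pytest.raises(RefAlleleMismatchError):
            score_variant(stub, sequences, self._features(toy_mcfg),
                          Variant("chr1", pos, wrong, "A", "rs1"), ["m"])


class TestMungeHqtl:
    def test_trans_removed(self):
        v = mkvar()
        kept = munge_hqtl([mkrec(v, peak_chrom="chr2")], receptive_field=10_000)
        assert kept == []

    def test_boundary_distance_retained(self):
        v = mkvar(pos=1000)
        rf = 500
        at_boundary = mkrec(v, start=1501, end=1600)   # gap exactly 501-1? compute
        # gap = peak_start - pos = 501 > 500 -> removed; 500 -> kept
        removed = munge_hqtl([mkrec(v, start=1501, end=1600)], rf)
        kept = munge_hqtl([mkrec(v, start=1500, end=1600)], rf)
        assert removed == [] and len(kept) == 1

    def test_hand_counted_decoy_mixture(self):
        vs = [mkvar(pos=1000 + i, vid=f"rs{i}") for i in range(10)]
        records = []
        for i, v in enumerate(vs):
            if i < 3:       # trans
                records.append(mkrec(v, peak_chrom="chr9"))
            elif i < 5:     # too far
                records.append(mkrec(v, start=500_000, end=500_100))
            elif i < 6:     # off whitelist (handled via whitelist arg)
                records.append(mkrec(v, start=900, end=1100))
            else:
                records.append(mkrec(v, start=900, end=1100))
        whitelist = {v.id for v in vs} - {"rs5"}
        kept = munge_hqtl(records, receptive_field=10_000, whitelist=whitelist)
        assert len(kept) == 4

    def test_snp_inside_peak_distance_zero(self):
        v = mkvar(pos=1000)
        kept = munge_hqtl([mkrec(v, start=900, end=1100)], receptive_field=0)
        assert len(kept) == 1


class TestAggregate:
    def test_single_peak_identity(self):
        m = aggregate_marginal([mkrec(mkvar(), beta=0.3)])
        assert m.alpha == pytest.approx(0.3)
        assert m.n_peaks == 1

    def test_four_unit_betas(self):
        v = mkvar()
        m = aggregate_marginal([mkrec(v, beta=1.0) for _ in range(4)])
        assert m.alpha == pytest.approx(2.0)  # 4 / sqrt(4)

    def test_matches_loop_oracle_on_random_groups(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            betas = rng.normal(size=n)
            v = mkvar()
            m = aggregate_marginal([mkrec(v, beta=b) for b in betas])
            oracle = sum(betas) / np.sqrt(n)
            assert abs(m.alpha - oracle) < 1e-12

    def test_mixed_snps_rejected(self):
        with pytest.raises(ConfigError):
            aggregate_marginal([mkrec(mkvar(vid="a")), mkrec(mkvar(vid="b"))])


def _score(v, value, mark="m"):
    return SnpEffectScore(v, {mark: value}, "cellX", 24)


class TestExportAndConcord:
    def test_identical_signs_full_concordance(self, tmp_path):
        vs = [mkvar(vid=f"rs{i}") for i in range(20)]
        vals = np.linspace(-1, 1, 20)
        vals[vals == 0] = 0.1
        scores = [_score(v, x) for v, x in zip(vs, vals)]
        margs = [AggregatedMarginal(v, x, 1) for v, x in zip(vs, vals)]
        rep = export_and_concord(scores, margs, "m", tmp_path / "ss.tsv")
        assert rep.sign_concordance == 1.0
        assert rep.rank_correlation == pytest.approx(1.0)
        header = (tmp_path / "ss.tsv").read_text().splitlines()[0]
        assert header.split("\t") == ["SNP", "A1", "A2", "Z"]

    def test_negated_signs_zero_concordance(self):
        vs = [mkvar(vid=f"rs{i}") for i in range(10)]
        vals = np.linspace(1, 2, 10)
        scores = [_score(v, x) for v, x in zip(vs, vals)]
        margs = [AggregatedMarginal(v, -x, 1) for v, x in zip(vs, vals)]
        rep = export_and_concord(scores, margs, "m")
        assert rep.sign_concordance == 0.0

    def test_random_signs_not_significant(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            vs = [mkvar(vid=f"rs{i}") for i in range(1000)]
            scores = [_score(v, rng.choice([-1.0, 1.0])) for v in vs]
            margs = [AggregatedMarginal(v, rng.choice([-1.0, 1.0]), 1) for v in vs]
            rep = export_and_concord(scores, margs, "m")
            assert rep.binomial_p > 0.05

    def test_empty_join_rejected(self):
        with pytest.raises(EmptyJoinError):
            export_and_concord([_score(mkvar(vid="a"), 1.0)],
                               [AggregatedMarginal(mkvar(vid="b"), 1.0, 1)], "m")

    def test_aggregate_all_groups_by_snp(self):
        va, vb = mkvar(vid="a"), mkvar(vid="b")
        out = aggregate_all([mkrec(va, beta=1.0), mkrec(vb, beta=2.0),
                             mkrec(va, beta=1.0)])
        alphas = {m.variant.id: m.alpha for m in out}
        assert alphas["a"] == pytest.approx(2 / np.sqrt(2))
        assert alphas["b"] == pytest.approx(2.0)
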