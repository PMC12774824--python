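"""Window scan, bucket partition, and chimeric panel assembly."""

import numpy as np
import pytest

from chimpanel.errors import PanelScanError, ValidationError
from chimpanel.maskgen import mask_genotypes
from chimpanel.panel import (
    PanelConfig,
    assemble_panel,
    build_panel,
    complete_samples,
    scan_windows,
)
from chimpanel.vcfio import MISSING

from conftest import make_matrix, random_matrix


def brute_force_scan(m, cfg):
    """Independent oracle: per-sample python scan + prefix shrinking.

    For each window (anchored at the first unbucketed site, spanning
    window_size bp), evaluate every prefix of its sites by exhaustively
    checking each sample for missing calls, and keep the longest prefix with
    at least ``required`` complete samples.
    """
    required = cfg.required
    out = []
    j = 0
    while j < m.n_sites:
        anchor = int(m.positions[j])
        in_window = [
            k for k in range(j, m.n_sites)
            if m.positions[k] <= anchor + cfg.window_size - 1
        ]
        chosen = None
        for end in range(len(in_window), 0, -1):
            sites = in_window[:end]
            complete = [
                i for i in range(m.n_samples)
                if all(m.calls[i, k, 0] != MISSING for k in sites)
            ]
            if len(complete) >= required:
                chosen = (sites, complete)
                break
        if chosen is None:
            sites = in_window[:1]
            n_ok = sum(
                all(m.calls[i, k, 0] != MISSING for k in sites)
                for i in range(m.n_samples)
            )
            raise PanelScanError(m.chrom, int(m.positions[sites[0]]), n_ok, required)
        out.append(chosen)
        j = chosen[0][-1] + 1
    return out


class TestCompleteSamples:
    def test_no_missing_returns_all(self):
        m = make_matrix([[(0, 1), (1, 1)], [(0, 0), (1, 0)]])
        assert complete_samples(m, [0, 1]).tolist() == [0, 1]

    def test_fig_style_window(self):
        # S3 and S5 have a gap somewhere in the window -> {S1, S2, S4}
        m = make_matrix(
            [
                [(0, 1), (1, 1)],
                [(0, 0), (0, 1)],
                [None, (1, 1)],
                [(1, 1), (0, 0)],
                [(0, 1), None],
            ]
        )
        assert complete_samples(m, [0, 1]).tolist() == [0, 1, 3]

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = random_matrix(rng, 6, 4, miss_rate=0.3)
            expected = [
                i for i in range(6)
                if all(m.calls[i, j, 0] != MISSING for j in range(4))
            ]
            assert complete_samples(m, range(4)).tolist() == expected


class TestScanWindows:
    def test_single_window_no_shrink(self):
        # 7 sites inside one 1000 bp window, no missing data, K=3
        m = make_matrix(
            [[(0, 1)] * 7 for _ in range(5)],
            positions=[10, 50, 200, 300, 500, 800, 1000],
        )
        buckets = scan_windows(m, PanelConfig(window_size=1000, panel_size=3))
        assert len(buckets) == 1
        assert buckets[0].site_indices.tolist() == list(range(7))
        assert buckets[0].complete_samples.tolist() == list(range(5))

    def test_shrink_then_error_on_reencounter(self):
        # completeness per site: s1=5, s2=5, s3=2 with K=3; all in one window
        rows = []
        for i in range(5):
            rows.append([(0, 1), (1, 0), (0, 0) if i < 2 else None])
        m = make_matrix(rows, positions=[100, 200, 300])
        cfg = PanelConfig(window_size=1000, panel_size=3)
        with pytest.raises(PanelScanError) as exc:
            scan_windows(m, cfg)
        assert exc.value.position == 300
        assert exc.value.n_complete == 2
        # the first bucket (s1, s2) was formed before termination:
        oracle_err = pytest.raises(PanelScanError)
        with oracle_err:
            brute_force_scan(m, cfg)

    def test_error_names_position_when_single_site_insufficient(self):
        m = make_matrix([[None], [(0, 0)], [None]], positions=[42])
        with pytest.raises(PanelScanError, match="42"):
            scan_windows(m, PanelConfig(window_size=10, panel_size=2))

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force_oracle(self, trial):
        """Scan equals the prefix-shrinking oracle on random small matrices,
        and errors iff some single site has < K complete samples."""
        rng = np.random.default_rng(100 + trial)
        n_samples = int(rng.integers(2, 9))
        n_sites = int(rng.integers(1, 21))
        m = random_matrix(
            rng, n_samples, n_sites,
            miss_rate=float(rng.uniform(0, 0.6)),
            spacing=int(rng.integers(1, 400)),
        )
        K = int(rng.integers(1, n_samples + 1))
        cfg = PanelConfig(window_size=int(rng.integers(1, 1200)), panel_size=K)
        per_site_complete = (m.calls[:, :, 0] != MISSING).sum(axis=0)
        should_fail = bool((per_site_complete < K).any())
        if should_fail:
            with pytest.raises(PanelScanError):
                scan_windows(m, cfg)
            with pytest.raises(PanelScanError):
                brute_force_scan(m, cfg)
            return
        buckets = scan_windows(m, cfg)
        oracle = brute_force_scan(m, cfg)
        assert [b.site_indices.tolist() for b in buckets] == [s for s, _ in oracle]
        assert [b.complete_samples.tolist() for b in buckets] == [
            c for _, c in oracle
        ]
        # partition property: contiguous, disjoint, exhaustive, ordered
        concat = np.concatenate([b.site_indices for b in buckets])
        assert concat.tolist() == list(range(n_sites))
        # interval bound
        for b in buckets:
            assert b.end_bp - b.start_bp + 1 <= cfg.window_size


class TestAssembleAndBuild:
    def test_forced_selection_when_pool_equals_k(self):
        m = make_matrix([[(0, 1)] * 3 for _ in range(4)])
        cfg = PanelConfig(window_size=100, panel_size=4, seed=9)
        panel = build_panel(m, cfg)
        for chosen in panel.provenance:
            assert sorted(chosen.tolist()) == [0, 1, 2, 3]

    def test_each_bucket_contributes_k_rows(self, small_cohort):
        cohort, _ = small_cohort
        masked, _ = mask_genotypes(cohort, 0.10, seed=4)
        cfg = PanelConfig(window_size=1000, panel_size=10, seed=1)
        panel = build_panel(masked, cfg)
        assert panel.matrix.n_samples == 10
        for chosen in panel.provenance:
            assert len(chosen) == 10
            assert len(set(chosen.tolist())) == 10  # without replacement

    def test_seeded_determinism_byte_identical_vcf(self, small_cohort, tmp_path):
        from chimpanel.vcfio import write_vcf

        cohort, _ = small_cohort
        masked, _ = mask_genotypes(cohort, 0.15, seed=4)
        cfg = PanelConfig(window_size=1000, panel_size=8, seed=21)
        p1 = build_panel(masked, cfg)
        p2 = build_panel(masked, cfg)
        f1, f2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(p1.matrix, f1)
        write_vcf(p2.matrix, f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_different_seed_same_sites(self, small_cohort):
        cohort, _ = small_cohort
        masked, _ = mask_genotypes(cohort, 0.15, seed=4)
        pa = build_panel(masked, PanelConfig(1000, 8, seed=1))
        pb = build_panel(masked, PanelConfig(1000, 8, seed=2))
        assert np.array_equal(pa.matrix.positions, pb.matrix.positions)
        assert pa.matrix.ref_allele.tolist() == pb.matrix.ref_allele.tolist()

    def test_panel_invariants_on_masked_cohort(self, small_cohort):
        """Zero missing calls and full site-set conservation."""
        cohort, _ = small_cohort
        masked, _ = mask_genotypes(cohort, 0.20, seed=8)
        panel = build_panel(masked, PanelConfig(1000, 10, seed=3))
        assert not np.any(panel.matrix.calls == MISSING)
        assert np.array_equal(panel.matrix.positions, cohort.positions)
        assert panel.matrix.chrom == cohort.chrom

    def test_k_larger_than_any_complete_count_errors(self):
        m = make_matrix([[(0, 1)], [None], [(0, 0)]])
        with pytest.raises((PanelScanError, ValidationError)):
            build_panel(m, PanelConfig(window_size=100, panel_size=3))

    def test_panel_size_bounds_validated(self):
        m = make_matrix([[(0, 1)], [(0, 0)]])
        with pytest.raises(ValidationError):
            build_panel(m, PanelConfig(window_size=100, panel_size=5))
        with pytest.raises(ValidationError):
            build_panel(m, PanelConfig(window_size=0, panel_size=1))
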