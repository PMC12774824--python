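"""Evaluation inputs: genotype masking, position dropping, and a cohort simulator.

Masking follows an all-or-nothing diploid model: both alleles of a selected
call are set missing, so no half of a heterozygote can leak information to the
imputer.  The masked-cell count is exact — ``floor(fraction * n_cells)`` cells
drawn among *currently observed* cells — and an optional per-site cap bounds
each site's total (pre-existing + new) missing fraction.  When the requested
fraction cannot fit under the cap the call fails loudly rather than silently
under-delivering; callers that deliberately mask beyond the cap (stress
scenarios) pass ``max_site_missing=None``.

The founder-mosaic simulator emulates a single-population diploid cohort:
each haplotype is a Markov mosaic over a small set of founder haplotypes
(switching founders between adjacent sites with a small probability and
flipping the copied allele with an even smaller one), which produces the
block-wise linkage disequilibrium and haplotype structure that makes
reference-panel imputation work in real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chimpanel.errors import InfeasibleMaskError, ValidationError
from chimpanel.vcfio import MISSING, GenotypeMatrix


@dataclass
class MaskRecord:
    """The exact cells masked, enabling truth comparison.

    ``cells`` is an (n_masked, 2) int array of (sample index, site index)
    rows, unique, all previously observed.
    """

    cells: np.ndarray
    fraction: float
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_tsv(self, m: GenotypeMatrix, path) -> None:
        with open(str(path), "w") as fh:
            fh.write("sample\tchrom\tpos\n")
            for i, j in self.cells:
                fh.write(f"{m.sample_ids[i]}\t{m.chrom}\t{m.positions[j]}\n")

    @classmethod
    def from_tsv(cls, m: GenotypeMatrix, path) -> "MaskRecord":
        sample_idx = {s: i for i, s in enumerate(m.sample_ids)}
        site_idx = {int(p): j for j, p in enumerate(m.positions)}
        cells = []
        with open(str(path)) as fh:
            next(fh)  # header
            for line in fh:
                s, _chrom, p = line.rstrip("\n").split("\t")
                cells.append((sample_idx[s], site_idx[int(p)]))
        arr = np.array(cells, dtype=np.int64).reshape(-1, 2)
        return cls(cells=arr, fraction=float("nan"), seed=-1)


def mask_genotypes(
    m: GenotypeMatrix,
    fraction: float,
    seed: int,
    max_site_missing: float | None = 0.20,
) -> tuple[GenotypeMatrix, MaskRecord]:
    """Randomly mask an exact count of observed diploid calls.

    Exactly ``floor(fraction * n_samples * n_sites)`` cells are drawn
    uniformly among currently observed cells, subject to the per-site cap:
    after masking, no site's total missing fraction exceeds
    ``max_site_missing`` (pass ``None`` to disable the cap).  Selection walks
    a seeded random permutation of the observed cells, skipping cells at
    sites whose budget is exhausted — this hits the exact global count
    whenever it is feasible at all.

    Returns the masked copy and a :class:`MaskRecord`.

    Raises
    ------
    InfeasibleMaskError
        If the summed per-site budgets cannot hold the requested count.
    ValidationError
        If ``fraction`` is outside [0, 0.30].
    """
    if not (0.0 <= fraction <= 0.30):
        raise ValidationError("masking fraction must be in [0, 0.30]")
    n, s = m.n_samples, m.n_sites
    target = int(np.floor(fraction * n * s))
    out = m.copy()
    if target == 0:
        return out, MaskRecord(
            cells=np.empty((0, 2), dtype=np.int64), fraction=fraction, seed=seed
        )

    missing_per_site = m.missing_mask().sum(axis=0)
    if max_site_missing is None:
        budget = np.full(s, n, dtype=np.int64) - missing_per_site
    else:
        budget = np.floor(max_site_missing * n).astype(np.int64) - missing_per_site
        budget = np.maximum(budget, 0)
    if budget.sum() < target:
        raise InfeasibleMaskError(
            f"cannot mask {target} cells: per-site cap "
            f"{max_site_missing} leaves a total budget of {int(budget.sum())}"
        )

    rng = np.random.default_rng(seed)
    obs_i, obs_j = np.nonzero(m.observed_mask())
    order = rng.permutation(len(obs_i))
    remaining = budget.copy()
    chosen = np.empty((target, 2), dtype=np.int64)
    k = 0
    for t in order:
        j = obs_j[t]
        if remaining[j] == 0:
            continue
        remaining[j] -= 1
        chosen[k] = (obs_i[t], j)
        k += 1
        if k == target:
            break
    if k < target:  # observed cells themselves ran out under the cap
        raise InfeasibleMaskError(
            f"only {k} observed cells available under the per-site cap, "
            f"{target} requested"
        )
    out.calls[chosen[:, 0], chosen[:, 1]] = MISSING
    out.phased[chosen[:, 0], chosen[:, 1]] = False
    return out, MaskRecord(cells=chosen, fraction=fraction, seed=seed)


def drop_positions(
    m: GenotypeMatrix, fraction: float, seed: int
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Remove a uniform random ``floor(fraction * n_sites)`` sites.

    Models an external reference panel that lacks some of the target's
    positions ("novel variants").  Site order is preserved among survivors.
    Returns the reduced matrix and the sorted dropped site indices.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValidationError("drop fraction must be in [0, 1)")
    n_drop = int(np.floor(fraction * m.n_sites))
    if n_drop == 0:
        return m.copy(), np.empty(0, dtype=np.int64)
    rng = np.random.default_rng(seed)
    dropped = np.sort(rng.choice(m.n_sites, size=n_drop, replace=False))
    keep = np.setdiff1d(np.arange(m.n_sites), dropped)
    return m.select_sites(keep), dropped


@dataclass
class MosaicParams:
    """Founder-mosaic cohort parameters.

    Defaults are the "benchmark" preset: 8 founders, 2,000 sites spaced
    500 bp apart (1 Mb total), 200 diploids, a founder-switch probability of
    0.002 per inter-site interval (mean block length ~250 kb), a per-site
    allele-flip probability of 5e-4, and founder allele frequencies drawn
    from Beta(0.5, 0.5) — a U-shaped frequency law giving a realistic excess
    of low-frequency variants while keeping strong block LD.
    """

    n_founders: int = 8
    n_sites: int = 2000
    n_diploids: int = 200
    spacing_bp: int = 500
    switch_prob: float = 0.002
    flip_prob: float = 5e-4
    founder_maf_law: tuple[float, float] = (0.5, 0.5)  # Beta(a, b)
    seed: int = 0
    chrom: str = "chr1"

    def check(self) -> None:
        if self.n_sites <= 0:
            raise ValidationError("n_sites must be positive")
        if self.n_founders < 2:
            raise ValidationError("n_founders must be >= 2")
        for p in (self.switch_prob, self.flip_prob):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must lie in [0, 1]")


def simulate_cohort(p: MosaicParams) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate a fully observed, fully phased single-population cohort.

    Founder haplotypes are drawn per site with frequency from
    ``Beta(*founder_maf_law)``; each of the 2*n_diploids cohort haplotypes is
    a hidden-Markov mosaic over the founders (switch to a uniformly chosen
    founder with ``switch_prob`` per inter-site interval, then copy the
    founder allele, flipped with ``flip_prob``).  Positions are
    ``1 + i * spacing_bp``.

    Returns the cohort matrix and the (n_founders, n_sites) founder
    haplotypes.
    """
    p.check()
    rng = np.random.default_rng(p.seed)
    freqs = rng.beta(*p.founder_maf_law, size=p.n_sites)
    founders = (rng.random((p.n_founders, p.n_sites)) < freqs).astype(np.int8)

    n_haps = 2 * p.n_diploids
    # founder index path per haplotype, vectorized across haplotypes
    state = np.empty((n_haps, p.n_sites), dtype=np.int64)
    state[:, 0] = rng.integers(p.n_founders, size=n_haps)
    switches = rng.random((n_haps, p.n_sites - 1)) < p.switch_prob
    new_states = rng.integers(p.n_founders, size=(n_haps, p.n_sites - 1))
    for t in range(1, p.n_sites):
        state[:, t] = np.where(switches[:, t - 1], new_states[:, t - 1], state[:, t - 1])

    haps = founders[state, np.arange(p.n_sites)]
    flips = rng.random(haps.shape) < p.flip_prob
    haps = np.where(flips, 1 - haps, haps).astype(np.int8)

    calls = np.stack(
        [haps[0::2], haps[1::2]], axis=2
    )  # (n_diploids, n_sites, 2)
    m = GenotypeMatrix(
        chrom=p.chrom,
        positions=1 + np.arange(p.n_sites, dtype=np.int64) * p.spacing_bp,
        ref_allele=np.array(["A"] * p.n_sites, dtype=object),
        alt_allele=np.array(["T"] * p.n_sites, dtype=object),
        sample_ids=np.array(
            [f"SIM_{i + 1:04d}" for i in range(p.n_diploids)], dtype=object
        ),
        calls=calls,
        phased=np.ones((p.n_diploids, p.n_sites), dtype=bool),
    )
    return m, founders


def split_target_reference(
    m: GenotypeMatrix, n_target: int, n_ref: int, seed: int
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Randomly split a cohort into disjoint target and external-panel sets."""
    if n_target + n_ref > m.n_samples:
        raise ValidationError(
            f"cannot split {m.n_samples} samples into {n_target} + {n_ref}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m.n_samples)
    t_idx = np.sort(perm[:n_target])
    r_idx = np.sort(perm[n_target : n_target + n_ref])
    return m.select_samples(t_idx), m.select_samples(r_idx)
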