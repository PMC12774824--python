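"""Chimeric reference-panel assembly.

The scan walks the contig left to right with a nonoverlapping window of
``window_size`` bp.  Within the current window it collects the samples with no
missing call at any variant site; if fewer than the required panel size
qualify, the window shrinks from its right edge until enough do.  Shrinking is
implemented as dropping the rightmost *variant site* rather than literal 1-bp
decrements: a decrement that removes no site cannot change the complete-sample
set, so the two are equivalent and the site-dropping form skips the no-op
iterations.  Each surviving window becomes a :class:`Bucket`; the next window
is anchored immediately after the last site the bucket kept, so sites shrunk
off the right edge are re-processed and the buckets partition the full site
set.  If shrinking bottoms out at a single site with too few complete samples
the scan terminates with :class:`~chimpanel.errors.PanelScanError` naming the
position — the remedy is stricter input filtering or a smaller panel.

Assembly then draws, per bucket, a seeded uniform sample of ``panel_size``
complete individuals without replacement and concatenates their genotype
blocks in genomic order into pseudo-samples ``CHIMERIC_0001 ...``.  The
resulting panel has zero missing calls and exactly the input's site set, so
no target variant is ever "novel" with respect to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chimpanel.errors import PanelScanError, ValidationError
from chimpanel.vcfio import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class PanelConfig:
    """Parameters of the window scan and panel assembly.

    window_size
        Initial (maximal) window length in bp; 1-based inclusive intervals.
        Default 1000 bp.
    panel_size
        Number K of chimeric pseudo-individuals to emit.
    min_complete
        Minimum complete samples a window must retain; defaults to
        ``panel_size`` (the two are collapsed unless overridden).
    seed
        Seed for the per-bucket random selection.
    """

    window_size: int = 1000
    panel_size: int = 50
    seed: int = 0
    min_complete: int | None = None

    @property
    def required(self) -> int:
        return self.panel_size if self.min_complete is None else self.min_complete

    def check(self, n_samples: int) -> None:
        if self.window_size < 1:
            raise ValidationError("window_size must be >= 1 bp")
        if not (1 <= self.panel_size <= n_samples):
            raise ValidationError(
                f"panel_size must be in [1, n_samples={n_samples}]"
            )
        if self.required < self.panel_size:
            raise ValidationError("min_complete cannot be below panel_size")


@dataclass
class Bucket:
    """A complete-genotype partition harvested from one (possibly shrunk) window.

    ``start_bp``/``end_bp`` are the first and last included site positions
    (1-based inclusive); ``site_indices`` is the contiguous run of site
    indices; ``complete_samples`` the sorted sample indices with no missing
    call across those sites.
    """

    start_bp: int
    end_bp: int
    site_indices: np.ndarray
    complete_samples: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)


@dataclass
class ChimericPanel:
    """K pseudo-individuals assembled bucket by bucket.

    ``matrix`` has zero missing calls and the same (chrom, positions, alleles)
    as the input; ``provenance`` records, per bucket, the source sample index
    occupying each panel slot.
    """

    matrix: GenotypeMatrix
    buckets: list[Bucket]
    provenance: list[np.ndarray] = field(default_factory=list)


def complete_samples(m: GenotypeMatrix, site_range) -> np.ndarray:
    """Sample indices with no missing call at any site in ``site_range``.

    ``site_range`` is a non-empty sequence of site indices.
    """
    idx = np.asarray(site_range)
    if idx.size == 0:
        raise ValidationError("site_range must be non-empty")
    ok = (m.calls[:, idx, 0] != MISSING).all(axis=1)
    return np.flatnonzero(ok)


def scan_windows(m: GenotypeMatrix, cfg: PanelConfig) -> list[Bucket]:
    """Partition all sites into buckets of complete-genotype partitions.

    See the module docstring for the scan/shrink semantics.  Windows holding
    zero variant sites are skipped by advancing the anchor to the next site.

    Raises
    ------
    PanelScanError
        When a single site has fewer complete samples than required.
    """
    m.validate()
    cfg.check(m.n_samples)
    required = cfg.required
    W = cfg.window_size
    pos = m.positions
    observed = m.calls[:, :, 0] != MISSING  # (n_samples, n_sites)

    buckets: list[Bucket] = []
    j = 0  # index of first site not yet bucketed
    n_sites = m.n_sites
    while j < n_sites:
        anchor = pos[j]  # empty-window skip: jump straight to the next site
        lo = j
        hi = int(np.searchsorted(pos, anchor + W - 1, side="right"))  # exclusive
        # shrink from the right edge until enough complete samples remain
        while True:
            ok = observed[:, lo:hi].all(axis=1)
            n_ok = int(ok.sum())
            if n_ok >= required:
                break
            if hi - lo == 1:
                raise PanelScanError(m.chrom, int(pos[lo]), n_ok, required)
            hi -= 1
        buckets.append(
            Bucket(
                start_bp=int(pos[lo]),
                end_bp=int(pos[hi - 1]),
                site_indices=np.arange(lo, hi),
                complete_samples=np.flatnonzero(ok),
            )
        )
        j = hi
    return buckets


def assemble_panel(
    m: GenotypeMatrix, buckets: list[Bucket], cfg: PanelConfig
) -> ChimericPanel:
    """Draw K individuals per bucket (seeded, without replacement) and concatenate.

    Panel slot order is draw order; genotype values and phase separators are
    copied verbatim from the source calls.
    """
    K = cfg.panel_size
    rng = np.random.default_rng(cfg.seed)
    calls = np.empty((K, m.n_sites, 2), dtype=m.calls.dtype)
    phased = np.zeros((K, m.n_sites), dtype=bool)
    provenance: list[np.ndarray] = []
    for b in buckets:
        if len(b.complete_samples) < K:
            raise ValidationError(
                f"bucket {m.chrom}:{b.start_bp}-{b.end_bp} has fewer complete "
                f"samples ({len(b.complete_samples)}) than panel_size {K}"
            )
        chosen = rng.choice(b.complete_samples, size=K, replace=False)
        provenance.append(chosen)
        sl = b.site_indices
        calls[:, sl] = m.calls[chosen][:, sl]
        phased[:, sl] = m.phased[chosen][:, sl]
    panel = GenotypeMatrix(
        chrom=m.chrom,
        positions=m.positions.copy(),
        ref_allele=m.ref_allele.copy(),
        alt_allele=m.alt_allele.copy(),
        sample_ids=np.array(
            [f"CHIMERIC_{k + 1:04d}" for k in range(K)], dtype=object
        ),
        calls=calls,
        phased=phased,
    )
    return ChimericPanel(matrix=panel, buckets=buckets, provenance=provenance)


def build_panel(m: GenotypeMatrix, cfg: PanelConfig) -> ChimericPanel:
    """Scan the contig and assemble the chimeric panel in one call."""
    return assemble_panel(m, scan_windows(m, cfg), cfg)


def write_provenance(panel: ChimericPanel, source: GenotypeMatrix, path) -> None:
    """Tab-separated sidecar: bucket_start, bucket_end, slot, source_sample."""
    with open(str(path), "w") as fh:
        fh.write("bucket_start\tbucket_end\tslot\tsource_sample\n")
        for b, chosen in zip(panel.buckets, panel.provenance):
            for slot, src in enumerate(chosen):
                fh.write(
                    f"{b.start_bp}\t{b.end_bp}\t{slot}\t{source.sample_ids[src]}\n"
                )
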