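"""VCF input/output and the in-memory genotype matrix.

One :class:`GenotypeMatrix` holds one contig of one VCF: an
``(n_samples, n_sites, 2)`` array of allele codes with ``-3`` as the missing
sentinel, plus a per-call phase flag mirroring the ``|`` vs ``/`` separator.
Calls are all-or-nothing: a half-called genotype like ``0/.`` is coerced to
fully missing on read, because downstream masking and panel construction model
a diploid call as present or absent as a unit.

Parsing is delegated to :mod:`cyvcf2`; writing emits a minimal GT-only VCF
v4.2 (optionally bgzip-compressed via pysam) since only the GT field is
consumed anywhere in the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from chimpanel.errors import ValidationError

#: Sentinel for a missing allele call.
MISSING: int = -3


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for one contig.

    Attributes
    ----------
    chrom : str
        Contig identifier; exactly one contig per matrix.
    positions : ndarray of int64, shape (n_sites,)
        1-based bp coordinates, strictly increasing (VCF convention).
    ref_allele, alt_allele : ndarray of str, shape (n_sites,)
        Per-site allele strings.  ``alt_allele`` may hold a comma-joined
        list before multiallelic filtering.
    sample_ids : ndarray of str, shape (n_samples,)
        Unique, ordered sample names.
    calls : ndarray of int8, shape (n_samples, n_sites, 2)
        Allele codes; both entries are in {0, 1, ...} or both are ``MISSING``.
    phased : ndarray of bool, shape (n_samples, n_sites)
        True where the call used the ``|`` separator; False for missing calls.
    """

    chrom: str
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    sample_ids: np.ndarray
    calls: np.ndarray
    phased: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_sites) — True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def observed_mask(self) -> np.ndarray:
        return ~self.missing_mask()

    def is_biallelic(self) -> np.ndarray:
        """Per-site flag: exactly one REF and one non-symbolic ALT allele."""
        return np.array(
            [("," not in a) and a not in (".", "") for a in self.alt_allele],
            dtype=bool,
        )

    def site_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().sum(axis=0) / self.n_samples

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
            sample_ids=self.sample_ids.copy(),
            calls=self.calls.copy(),
            phased=self.phased.copy(),
        )

    def select_sites(self, idx) -> "GenotypeMatrix":
        """Sub-matrix at the given site indices (order preserved as given)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            sample_ids=self.sample_ids.copy(),
            calls=self.calls[:, idx],
            phased=self.phased[:, idx],
        )

    def select_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
            sample_ids=self.sample_ids[idx],
            calls=self.calls[idx],
            phased=self.phased[idx],
        )

    def validate(self) -> None:
        """Check structural invariants; raise ValidationError on violation."""
        if self.calls.shape != (self.n_samples, self.n_sites, 2):
            raise ValidationError("calls shape mismatch")
        if self.phased.shape != (self.n_samples, self.n_sites):
            raise ValidationError("phased shape mismatch")
        if self.n_sites and np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if len(set(self.sample_ids.tolist())) != self.n_samples:
            raise ValidationError("sample_ids must be unique")
        a, b = self.calls[:, :, 0], self.calls[:, :, 1]
        half = (a == MISSING) != (b == MISSING)
        if np.any(half):
            raise ValidationError("half-calls present; calls must be all-or-nothing")


_FILEFORMAT_RE = re.compile(r"##fileformat=VCFv(\d+)\.(\d+)")


def _check_fileformat(raw_header: str) -> None:
    m = _FILEFORMAT_RE.search(raw_header)
    if m is None:
        raise ValidationError("VCF has no ##fileformat header line")
    major, minor = int(m.group(1)), int(m.group(2))
    if (major, minor) < (4, 0):
        raise ValidationError(
            f"VCF fileformat v{major}.{minor} is below the required v4.0"
        )


def read_vcf(path, chrom: str) -> GenotypeMatrix:
    """Read one contig of a VCF (v4.0+) into a :class:`GenotypeMatrix`.

    Only the GT FORMAT field is consumed.  Half-called genotypes are coerced
    to fully missing; phase separators are preserved per call.  Symbolic
    ``<NON_REF>`` alleles (GVCF reference blocks) are rejected.

    Parameters
    ----------
    path : str or Path
        Plain or bgzip-compressed VCF.
    chrom : str
        Contig to load; other contigs are ignored.

    Raises
    ------
    ValidationError
        Unreadable file, fileformat below 4.0, non-diploid GT, GVCF symbolic
        alleles, or no records on ``chrom``.
    """
    path = str(path)
    if not Path(path).exists():
        raise ValidationError(f"no such file: {path}")
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ValidationError(f"cannot parse VCF {path}: {exc}") from exc
    _check_fileformat(vcf.raw_header)
    sample_ids = np.array(vcf.samples, dtype=object)
    n = len(sample_ids)

    positions, refs, alts = [], [], []
    call_rows, phase_rows = [], []
    for v in vcf:
        if v.CHROM != chrom:
            continue
        if any(a == "<NON_REF>" for a in v.ALT):
            raise ValidationError(
                f"GVCF symbolic allele <NON_REF> at {v.CHROM}:{v.POS}; "
                "GVCF reference blocks are not supported"
            )
        gts = v.genotypes  # list of [a0, a1, ..., phased]
        col = np.empty((n, 2), dtype=np.int8)
        pcol = np.zeros(n, dtype=bool)
        for i, g in enumerate(gts):
            if len(g) != 3:
                raise ValidationError(
                    f"non-diploid genotype (ploidy {len(g) - 1}) for sample "
                    f"{sample_ids[i]} at {v.CHROM}:{v.POS}"
                )
            a0, a1, ph = g
            if a0 < 0 or a1 < 0:  # missing or half-call -> fully missing
                col[i] = (MISSING, MISSING)
                pcol[i] = False
            else:
                col[i] = (a0, a1)
                pcol[i] = bool(ph)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(",".join(v.ALT) if v.ALT else ".")
        call_rows.append(col)
        phase_rows.append(pcol)
    vcf.close()

    if not positions:
        raise ValidationError(f"contig {chrom!r} has no records in {path}")
    m = GenotypeMatrix(
        chrom=chrom,
        positions=np.array(positions, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        sample_ids=sample_ids,
        calls=np.stack(call_rows, axis=1),
        phased=np.stack(phase_rows, axis=1),
    )
    m.validate()
    return m


@dataclass
class FilterReport:
    """Sites removed by :func:`validate_and_filter` and why."""

    removed_multiallelic: list = field(default_factory=list)  # (index, pos)
    removed_missingness: list = field(default_factory=list)  # (index, pos, frac)

    @property
    def n_removed(self) -> int:
        return len(self.removed_multiallelic) + len(self.removed_missingness)


def validate_and_filter(
    m: GenotypeMatrix,
    max_site_missing: float = 0.20,
    drop_multiallelic: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Restrict a matrix to biallelic sites with tolerable missingness.

    Sites failing either rule — more than one ALT allele, or a missing-call
    fraction above ``max_site_missing`` (default 20%) — are removed and listed
    in the report.  Idempotent; never reorders samples or sites.

    Raises
    ------
    ValidationError
        If ``drop_multiallelic`` is False and a multiallelic site is present.
    """
    m.validate()
    report = FilterReport()
    biallelic = m.is_biallelic()
    if not drop_multiallelic and not biallelic.all():
        bad = int(np.flatnonzero(~biallelic)[0])
        raise ValidationError(
            f"multiallelic site at {m.chrom}:{m.positions[bad]} "
            "(drop_multiallelic=False)"
        )
    frac = m.site_missing_fraction()
    keep = np.ones(m.n_sites, dtype=bool)
    for j in range(m.n_sites):
        if not biallelic[j]:
            report.removed_multiallelic.append((j, int(m.positions[j])))
            keep[j] = False
        elif frac[j] > max_site_missing:
            report.removed_missingness.append((j, int(m.positions[j]), float(frac[j])))
            keep[j] = False
    if keep.all():
        return m, report
    return m.select_sites(np.flatnonzero(keep)), report


def _gt_string(a0: int, a1: int, phased: bool, force_phased: bool) -> str:
    if a0 == MISSING:
        return "./."
    sep = "|" if (phased or force_phased) else "/"
    return f"{a0}{sep}{a1}"


def write_vcf(m: GenotypeMatrix, path, phased_output: bool = False) -> None:
    """Write a matrix as a GT-only VCF v4.2.

    Missing calls are written ``./.``; with ``phased_output`` every observed
    call uses the ``|`` separator.  A ``.gz`` suffix triggers bgzip
    compression so the output stays readable by htslib-based tools.
    """
    m.validate()
    path = str(path)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={m.chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(s) for s in m.sample_ids),
    ]
    calls = m.calls
    phased = m.phased
    for j in range(m.n_sites):
        gts = "\t".join(
            _gt_string(
                int(calls[i, j, 0]), int(calls[i, j, 1]),
                bool(phased[i, j]), phased_output,
            )
            for i in range(m.n_samples)
        )
        lines.append(
            f"{m.chrom}\t{m.positions[j]}\t.\t{m.ref_allele[j]}\t"
            f"{m.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}"
        )
    text = "\n".join(lines) + "\n"
    if path.endswith(".gz"):
        import pysam

        with pysam.BGZFile(path, "wb") as fh:
            fh.write(text.encode())
    else:
        try:
            with open(path, "w") as fh:
                fh.write(text)
        except OSError as exc:
            raise ValidationError(f"cannot write {path}: {exc}") from exc
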