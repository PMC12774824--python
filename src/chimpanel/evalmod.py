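"""Phase-aware imputation accuracy, MAC stratification, replicate aggregation.

Accuracy is scored only at masked cells, against the original unmasked truth,
under a strict phase-aware criterion: the imputed ordered allele pair must
match the truth exactly, so an imputed 1|0 against a true 0|1 is *incorrect*
even though the dosage agrees.  (If the truth call itself is unphased the
comparison falls back to unordered, since no phase is defined to violate.)
Cells that come back still missing — including cells at sites the engine
discarded because the reference panel lacked them — count as incorrect:
information loss is penalised, not excused.

Per-site accuracies are stratified by the minor allele count (MAC) computed
from the original unmasked matrix; bins use a closed-left convention (a MAC
equal to a bin edge goes to the lower bin).  Replicates are summarised as
mean ± standard error (sd/sqrt(n)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from chimpanel.errors import ValidationError
from chimpanel.maskgen import MaskRecord
from chimpanel.vcfio import MISSING, GenotypeMatrix

#: default MAC bin upper edges: <=2, 3-5, 6-10, 11-20, 21-50, 51-100, >100
DEFAULT_MAC_EDGES: tuple[int, ...] = (2, 5, 10, 20, 50, 100)


def genotype_correct(truth, imputed) -> bool:
    """Strict phase-aware correctness of one diploid call.

    ``truth`` and ``imputed`` are (a0, a1, phased) triples; the allele pair
    must match as an *ordered* pair when the truth is phased, as an unordered
    pair otherwise.  A missing imputed call is incorrect.  A missing truth
    call is an error — accuracy is only defined where the truth is known.
    """
    ta0, ta1, tph = int(truth[0]), int(truth[1]), bool(truth[2])
    ia0, ia1 = int(imputed[0]), int(imputed[1])
    if ta0 == MISSING:
        raise ValidationError("truth call is missing; cannot score")
    if ia0 == MISSING:
        return False
    if tph:
        return (ta0, ta1) == (ia0, ia1)
    return {ta0, ta1} == {ia0, ia1} and ta0 + ta1 == ia0 + ia1


@dataclass
class AccuracyReport:
    """Accuracy among masked cells, overall and per site.

    ``per_site`` maps site index -> (n_masked, n_correct, accuracy) for sites
    with at least one masked cell; ``per_site_mac`` carries the MAC from the
    unmasked truth; ``overall`` is cell-weighted (sum correct / sum masked)
    and ``site_averaged`` the unweighted mean of per-site accuracies.
    """

    overall: float
    site_averaged: float
    per_site: dict = field(default_factory=dict)
    per_site_mac: dict = field(default_factory=dict)
    n_cells: int = 0
    n_correct: int = 0

    def to_json(self, path) -> None:
        payload = {
            "overall": self.overall,
            "site_averaged": self.site_averaged,
            "n_cells": self.n_cells,
            "n_correct": self.n_correct,
            "per_site": {
                str(k): {"n_masked": v[0], "n_correct": v[1], "accuracy": v[2]}
                for k, v in self.per_site.items()
            },
            "per_site_mac": {str(k): int(v) for k, v in self.per_site_mac.items()},
        }
        with open(str(path), "w") as fh:
            json.dump(payload, fh, indent=2)


def minor_allele_count(m: GenotypeMatrix, site: int) -> int:
    """min(#ref alleles, #alt alleles) over non-missing calls at a site."""
    col = m.calls[:, site]
    obs = col[col[:, 0] != MISSING]
    if obs.size == 0:
        raise ValidationError(f"site {site}: all calls missing, MAC undefined")
    n_alt = int((obs == 1).sum())
    n_ref = int((obs == 0).sum())
    return min(n_ref, n_alt)


def accuracy(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    mask: MaskRecord,
    uncovered_sites=None,
) -> AccuracyReport:
    """Score imputation at the masked cells only.

    ``uncovered_sites`` lists site indices the engine discarded (reference
    panel lacked them); masked cells there are counted incorrect regardless
    of what the imputed matrix holds.

    Raises ValidationError on sample/site mismatch between the matrices.
    """
    if truth.n_samples != imputed.n_samples or truth.n_sites != imputed.n_sites:
        raise ValidationError("truth and imputed matrices differ in shape")
    if not np.array_equal(truth.positions, imputed.positions):
        raise ValidationError("truth and imputed matrices differ in sites")
    if not np.array_equal(truth.sample_ids, imputed.sample_ids):
        raise ValidationError("truth and imputed matrices differ in samples")
    uncovered = set(int(u) for u in uncovered_sites) if uncovered_sites is not None else set()

    per_site_n: dict[int, int] = {}
    per_site_c: dict[int, int] = {}
    for i, j in mask.cells:
        i, j = int(i), int(j)
        t = (truth.calls[i, j, 0], truth.calls[i, j, 1], truth.phased[i, j])
        if j in uncovered:
            ok = False
        else:
            imp = (imputed.calls[i, j, 0], imputed.calls[i, j, 1], imputed.phased[i, j])
            ok = genotype_correct(t, imp)
        per_site_n[j] = per_site_n.get(j, 0) + 1
        per_site_c[j] = per_site_c.get(j, 0) + int(ok)

    n_cells = sum(per_site_n.values())
    n_correct = sum(per_site_c.values())
    per_site = {
        j: (per_site_n[j], per_site_c[j], per_site_c[j] / per_site_n[j])
        for j in sorted(per_site_n)
    }
    per_site_mac = {j: minor_allele_count(truth, j) for j in per_site}
    accs = [v[2] for v in per_site.values()]
    return AccuracyReport(
        overall=n_correct / n_cells if n_cells else 1.0,
        site_averaged=float(np.mean(accs)) if accs else 1.0,
        per_site=per_site,
        per_site_mac=per_site_mac,
        n_cells=n_cells,
        n_correct=n_correct,
    )


def bin_by_mac(report: AccuracyReport, edges=DEFAULT_MAC_EDGES) -> list[dict]:
    """Masked-cell-weighted accuracy per MAC bin.

    ``edges`` are increasing upper boundaries; a site whose MAC equals an
    edge falls in the lower bin (closed-left), and MACs above the last edge
    form the final open bin.  Returns one dict per non-empty-labelled bin:
    label, mac range, n_sites, n_cells, accuracy.
    """
    edges = list(edges)
    if not report.per_site:
        raise ValidationError("empty accuracy report; nothing to bin")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("MAC bin edges must be strictly increasing")
    bounds = [(0, edges[0])] + [
        (edges[k] + 1, edges[k + 1]) for k in range(len(edges) - 1)
    ] + [(edges[-1] + 1, None)]
    rows = []
    for lo, hi in bounds:
        label = f"{lo}-{hi}" if hi is not None else f">{lo - 1}"
        n_sites = n_cells = n_correct = 0
        for j, (nm, nc, _a) in report.per_site.items():
            mac = report.per_site_mac[j]
            if mac >= lo and (hi is None or mac <= hi):
                n_sites += 1
                n_cells += nm
                n_correct += nc
        rows.append(
            {
                "bin": label,
                "mac_min": lo,
                "mac_max": hi,
                "n_sites": n_sites,
                "n_cells": n_cells,
                "accuracy": (n_correct / n_cells) if n_cells else float("nan"),
            }
        )
    return rows


@dataclass
class ReplicateSummary:
    """Mean ± standard error of replicate overall accuracies."""

    overalls: list[float]
    mean: float
    se: float
    single_replicate: bool = False

    @property
    def n(self) -> int:
        return len(self.overalls)


def aggregate(reports) -> ReplicateSummary:
    """Summarise replicate reports (or bare accuracies) as mean and sd/sqrt(n).

    A single replicate yields se = 0 by convention, flagged via
    ``single_replicate``.
    """
    overalls = [
        r.overall if isinstance(r, AccuracyReport) else float(r) for r in reports
    ]
    if not overalls:
        raise ValidationError("aggregate needs at least one replicate")
    n = len(overalls)
    mean = float(np.mean(overalls))
    if n == 1:
        return ReplicateSummary(overalls, mean, 0.0, single_replicate=True)
    se = float(np.std(overalls, ddof=1) / np.sqrt(n))
    return ReplicateSummary(overalls, mean, se)


def dosage_accuracy(
    truth: GenotypeMatrix, imputed: GenotypeMatrix, mask: MaskRecord
) -> float:
    """Phase-agnostic (allele-dosage) accuracy at the masked cells.

    An imputed call is correct when its allele sum matches the truth's,
    regardless of order.  Upper-bounds the phase-aware metric on the same
    cells; provided for comparison with conventional dosage-based reports.
    """
    n = c = 0
    for i, j in mask.cells:
        i, j = int(i), int(j)
        n += 1
        if imputed.calls[i, j, 0] == MISSING:
            continue
        if int(truth.calls[i, j].sum()) == int(imputed.calls[i, j].sum()):
            c += 1
    return c / n if n else 1.0
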