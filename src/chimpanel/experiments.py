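"""End-to-end replicate experiment harness.

Each experiment cell is mask -> build panel -> impute -> evaluate on a common
cohort, replicated with independent mask/panel seeds (the design the accuracy
figures of reference-panel studies use: same cohort, different random masks,
mean ± SE over replicates).  The novel-variant experiment contrasts a chimeric
panel, which by construction carries every target site, against an external
panel from held-out individuals with a fraction of its positions removed;
masked cells at removed positions are scored incorrect for the external arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chimpanel.errors import ValidationError
from chimpanel.evalmod import AccuracyReport, accuracy, aggregate, bin_by_mac
from chimpanel.imputer import LSParams, impute_matrix
from chimpanel.maskgen import (
    MosaicParams,
    mask_genotypes,
    drop_positions,
    simulate_cohort,
    split_target_reference,
)
from chimpanel.panel import PanelConfig, build_panel
from chimpanel.vcfio import GenotypeMatrix


@dataclass
class ExperimentConfig:
    """Grid of masking fractions x panel sizes x window sizes, replicated.

    ``mask_cap`` is the per-site missingness cap passed to the masker; the
    default (None) disables it so any fraction up to 0.30 is deliverable —
    pass 0.20 to mirror the input-filtering rule instead.
    """

    fractions: list = field(default_factory=lambda: [0.10])
    panel_sizes: list = field(default_factory=lambda: [50])
    window_sizes: list = field(default_factory=lambda: [1000])
    replicates: int = 3
    seed: int = 1
    mask_cap: float | None = None
    ls_params: LSParams = field(default_factory=LSParams)

    def check(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if any(not (0 <= f <= 0.30) for f in self.fractions):
            raise ValidationError("masking fractions must lie in [0, 0.30]")


def _replicate_seeds(seed: int, n: int) -> list[tuple[int, int]]:
    """Deterministic (mask_seed, panel_seed) pairs derived from one seed."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n):
        a, b = child.generate_state(2)
        out.append((int(a % (2**31)), int(b % (2**31))))
    return out


def run_replicate(
    cohort: GenotypeMatrix,
    fraction: float,
    panel_size: int,
    window_size: int,
    mask_seed: int,
    panel_seed: int,
    mask_cap: float | None = None,
    ls_params: LSParams = LSParams(),
) -> AccuracyReport:
    """One experiment cell: mask the cohort, build a chimeric panel from the
    masked data itself, impute with the bundled engine, score at the mask."""
    masked, record = mask_genotypes(
        cohort, fraction, seed=mask_seed, max_site_missing=mask_cap
    )
    cfg = PanelConfig(
        window_size=window_size, panel_size=panel_size, seed=panel_seed
    )
    panel = build_panel(masked, cfg)
    imputed, uncovered = impute_matrix(masked, panel.matrix, ls_params)
    return accuracy(cohort, imputed, record, uncovered_sites=uncovered)


def run_experiment(
    cohort: GenotypeMatrix, cfg: ExperimentConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full grid; returns (per-replicate rows, per-cell summary rows).

    Row schema: fraction, panel_size, window_size, replicate, mask_seed,
    panel_seed, overall, site_averaged, n_cells.  Summary adds mean/se.
    """
    cfg.check()
    rows, summaries = [], []
    for fraction in cfg.fractions:
        for K in cfg.panel_sizes:
            for W in cfg.window_sizes:
                cell_seed = int(
                    np.random.SeedSequence(
                        [cfg.seed, int(round(fraction * 1000)), K, W]
                    ).generate_state(1)[0]
                    % (2**31)
                )
                reports = []
                for r, (ms, ps) in enumerate(
                    _replicate_seeds(cell_seed, cfg.replicates), start=1
                ):
                    try:
                        rep = run_replicate(
                            cohort, fraction, K, W, ms, ps,
                            mask_cap=cfg.mask_cap, ls_params=cfg.ls_params,
                        )
                    except ValidationError as exc:
                        raise ValidationError(
                            f"experiment cell fraction={fraction} K={K} W={W} "
                            f"replicate={r}: {exc}"
                        ) from exc
                    reports.append(rep)
                    rows.append(
                        dict(
                            fraction=fraction, panel_size=K, window_size=W,
                            replicate=r, mask_seed=ms, panel_seed=ps,
                            overall=rep.overall,
                            site_averaged=rep.site_averaged,
                            n_cells=rep.n_cells,
                        )
                    )
                summ = aggregate(reports)
                summaries.append(
                    dict(
                        fraction=fraction, panel_size=K, window_size=W,
                        replicates=cfg.replicates, mean=summ.mean, se=summ.se,
                    )
                )
    return pd.DataFrame(rows), pd.DataFrame(summaries)


def run_novel_variant_experiment(
    cohort: GenotypeMatrix,
    drop_fractions,
    n_target: int = 200,
    n_ref: int = 50,
    mask_fraction: float = 0.10,
    panel_size: int = 50,
    window_size: int = 1000,
    replicates: int = 3,
    seed: int = 1,
    ls_params: LSParams = LSParams(),
) -> pd.DataFrame:
    """External panel with dropped positions vs the chimeric panel.

    Per drop fraction and replicate: split the cohort into target and
    external-panel individuals, mask the target, drop random positions from
    the external panel, impute the target with both panels and score both
    arms with discarded-site cells counted incorrect (the external arm's
    coverage shortfall is exactly what the convention penalises).
    """
    split_seed = int(np.random.SeedSequence([seed, 17]).generate_state(1)[0] % 2**31)
    target_full, external = split_target_reference(
        cohort, n_target, n_ref, seed=split_seed
    )
    rows = []
    for dfrac in drop_fractions:
        for r, (mask_seed, aux_seed) in enumerate(
            _replicate_seeds(int(np.random.SeedSequence(
                [seed, int(round(dfrac * 1000))]).generate_state(1)[0] % 2**31),
                replicates),
            start=1,
        ):
            masked, record = mask_genotypes(
                target_full, mask_fraction, seed=mask_seed, max_site_missing=None
            )
            ext_panel, dropped = drop_positions(external, dfrac, seed=aux_seed)
            imp_ext, unc_ext = impute_matrix(masked, ext_panel, ls_params)
            rep_ext = accuracy(target_full, imp_ext, record, uncovered_sites=unc_ext)

            chim = build_panel(
                masked,
                PanelConfig(window_size=window_size, panel_size=panel_size,
                            seed=aux_seed),
            )
            imp_chi, unc_chi = impute_matrix(masked, chim.matrix, ls_params)
            rep_chi = accuracy(target_full, imp_chi, record, uncovered_sites=unc_chi)

            for arm, rep, unc in (
                ("external", rep_ext, unc_ext),
                ("chimeric", rep_chi, unc_chi),
            ):
                rows.append(
                    dict(
                        drop_fraction=dfrac, arm=arm, replicate=r,
                        mask_seed=mask_seed, aux_seed=aux_seed,
                        overall=rep.overall, n_cells=rep.n_cells,
                        site_coverage=1.0 - len(unc) / target_full.n_sites,
                    )
                )
    return pd.DataFrame(rows)


def benchmark_preset(seed: int = 0, **overrides) -> MosaicParams:
    """The default synthetic study conditions (see MosaicParams docstring)."""
    return MosaicParams(seed=seed, **overrides)


def simulate_preset_cohort(seed: int = 0, **overrides):
    return simulate_cohort(benchmark_preset(seed=seed, **overrides))


def mac_bin_table(report: AccuracyReport, edges=None) -> pd.DataFrame:
    from chimpanel.evalmod import DEFAULT_MAC_EDGES

    return pd.DataFrame(bin_by_mac(report, edges or DEFAULT_MAC_EDGES))
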