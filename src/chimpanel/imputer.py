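"""Bundled haplotype-copying imputer and external-engine plumbing.

The bundled engine is a classic Li–Stephens copying model: a query haplotype
is modelled as an imperfect mosaic of the panel haplotypes.  Hidden states are
the panel haplotypes; between adjacent sites at distance ``d`` bp the chain
stays put with probability ``exp(-rho*d)`` and otherwise jumps to a state
chosen uniformly (so the per-state switch mass is ``(1-exp(-rho*d))/S``);
emissions are ``1-eps`` on allele match, ``eps`` on mismatch, and 1 at missing
sites.  Posterior allele probabilities come from the scaled forward–backward
recursion; missing entries are filled with the posterior-weighted allele and
observed entries are returned unchanged.

Diploid targets are imputed as two independent haploid chains, which requires
phased input; phasing of unphased real data is the job of a full external
engine (an adapter for Beagle-style jars is provided), not of this bundled
desk-scale imputer.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from chimpanel.errors import ValidationError
from chimpanel.vcfio import MISSING, GenotypeMatrix

#: sentinel for a missing allele in a haplotype vector
HAP_MISSING: int = -1


@dataclass(frozen=True)
class LSParams:
    """Copying-model parameters.

    switch_rate
        Expected state switches per bp (rho).  The default 1e-6 corresponds
        to the 1 cM/Mb scale typical of many genomes.
    emission_error
        Miscopy probability (eps), in (0, 0.5).
    posterior_threshold
        Alternate-allele call threshold on the posterior; at exact equality
        the call goes to the reference allele (deterministic tie-break).
    """

    switch_rate: float = 1e-6
    emission_error: float = 1e-3
    posterior_threshold: float = 0.5

    def check(self) -> None:
        if not (0.0 < self.emission_error < 0.5):
            raise ValidationError("emission_error must be in (0, 0.5)")
        if self.switch_rate <= 0:
            raise ValidationError("switch_rate must be positive")


def _stay_probs(positions: np.ndarray, rho: float) -> np.ndarray:
    """exp(-rho*d) for the T-1 inter-site gaps."""
    d = np.diff(positions).astype(float)
    return np.exp(-rho * d)


def _emissions(obs: np.ndarray, panel: np.ndarray, eps: float) -> np.ndarray:
    """Emission matrix, shape (n_queries, T, S)."""
    obs3 = obs[:, :, None]
    match = panel.T[None, :, :] == obs3
    e = np.where(match, 1.0 - eps, eps)
    return np.where(obs3 == HAP_MISSING, 1.0, e)


def _forward_backward_batch(
    obs: np.ndarray, panel: np.ndarray, positions: np.ndarray, p: LSParams
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward–backward for a batch of query haplotypes.

    Parameters
    ----------
    obs : (n_queries, T) int array, alleles in {0,1} or HAP_MISSING
    panel : (S, T) int array of complete panel haplotypes

    Returns
    -------
    gamma : (n_queries, T, S) per-site state posteriors (rows sum to 1)
    p_alt : (n_queries, T) posterior probability of the alternate allele
    """
    nq, T = obs.shape
    S = panel.shape[0]
    eps = p.emission_error
    stay = _stay_probs(positions, p.switch_rate)
    E = _emissions(obs, panel, eps)

    f = np.empty((nq, T, S))
    f[:, 0] = E[:, 0] / S
    f[:, 0] /= f[:, 0].sum(axis=1, keepdims=True)
    for t in range(1, T):
        a = stay[t - 1]
        # rank-1 transition: stay on the diagonal, uniform jump elsewhere
        prior = a * f[:, t - 1] + (1.0 - a) / S
        ft = prior * E[:, t]
        f[:, t] = ft / ft.sum(axis=1, keepdims=True)

    b = np.ones((nq, S))
    gamma = np.empty((nq, T, S))
    g = f[:, T - 1] * b
    gamma[:, T - 1] = g / g.sum(axis=1, keepdims=True)
    for t in range(T - 2, -1, -1):
        a = stay[t]
        eb = E[:, t + 1] * b
        b = a * eb + (1.0 - a) * eb.mean(axis=1, keepdims=True)
        b /= b.sum(axis=1, keepdims=True)
        g = f[:, t] * b
        gamma[:, t] = g / g.sum(axis=1, keepdims=True)

    p_alt = np.einsum("qts,st->qt", gamma, panel.astype(float))
    return gamma, p_alt


def ls_impute_haplotype(
    obs: np.ndarray,
    panel_haps: np.ndarray,
    p: LSParams,
    site_positions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Impute one haplotype against a panel of complete haplotypes.

    Parameters
    ----------
    obs : (T,) int array
        Alleles in {0, 1} with ``HAP_MISSING`` (-1) at unobserved sites.
    panel_haps : (S, T) int array
        Complete panel haplotypes (no missing entries).
    p : LSParams
    site_positions : (T,) bp coordinates.

    Returns
    -------
    imputed : (T,) int array — observed entries unchanged, missing entries
        filled with the posterior call (alt iff p_alt > threshold).
    p_alt : (T,) posterior alternate-allele probabilities.
    gamma : (T, S) per-site state posteriors (each row sums to 1).
    """
    p.check()
    obs = np.asarray(obs)
    panel_haps = np.asarray(panel_haps)
    if panel_haps.ndim != 2 or panel_haps.shape[0] == 0:
        raise ValidationError("panel_haps must be a non-empty (S, T) array")
    if panel_haps.shape[1] != obs.shape[0] or len(site_positions) != obs.shape[0]:
        raise ValidationError("haplotype/panel/position length mismatch")
    gamma, p_alt = _forward_backward_batch(
        obs[None, :], panel_haps, np.asarray(site_positions), p
    )
    imputed = obs.copy()
    miss = obs == HAP_MISSING
    imputed[miss] = (p_alt[0][miss] > p.posterior_threshold).astype(imputed.dtype)
    return imputed, p_alt[0], gamma[0]


def _require_phased(m: GenotypeMatrix, what: str) -> None:
    unphased = m.observed_mask() & ~m.phased
    if np.any(unphased):
        i, j = np.argwhere(unphased)[0]
        raise ValidationError(
            f"{what} must be fully phased for the bundled imputer; sample "
            f"{m.sample_ids[i]} at {m.chrom}:{m.positions[j]} is unphased"
        )


def impute_matrix(
    target: GenotypeMatrix,
    panel: GenotypeMatrix,
    p: LSParams = LSParams(),
    chunk: int = 64,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Impute every missing call of a phased target from a complete panel.

    Each of the target's 2N haplotypes is imputed independently against the
    panel's 2K haplotypes at the panel's sites.  Target sites absent from the
    panel cannot be imputed and are left missing — the same discarding
    behaviour conventional engines show for variants the reference panel does
    not carry — and their site indices are returned.

    Returns the imputed matrix (phased at newly filled calls) and the sorted
    array of uncovered target site indices.
    """
    p.check()
    _require_phased(target, "target")
    if np.any(panel.missing_mask()):
        raise ValidationError("panel must contain no missing calls")
    _require_phased(panel, "panel")

    pos_to_idx = {int(q): j for j, q in enumerate(target.positions)}
    panel_in_target = []
    for q in panel.positions:
        j = pos_to_idx.get(int(q))
        if j is not None:
            panel_in_target.append(j)
    covered = np.array(sorted(panel_in_target), dtype=np.int64)
    uncovered = np.setdiff1d(np.arange(target.n_sites), covered)

    out = target.copy()
    if covered.size == 0:
        return out, uncovered

    # restrict to covered sites; panel may carry extra sites, drop them
    panel_keep = np.array(
        [k for k, q in enumerate(panel.positions) if int(q) in pos_to_idx],
        dtype=np.int64,
    )
    panel_sub = panel.select_sites(panel_keep)
    positions = panel_sub.positions
    # panel haplotypes: (2K, T)
    ph = np.concatenate(
        [panel_sub.calls[:, :, 0], panel_sub.calls[:, :, 1]], axis=0
    ).astype(np.int8)

    tcalls = target.calls[:, covered]  # (N, T, 2)
    haps = np.concatenate([tcalls[:, :, 0], tcalls[:, :, 1]], axis=0).astype(
        np.int16
    )
    haps[haps == MISSING] = HAP_MISSING

    n_haps = haps.shape[0]
    imputed = np.empty_like(haps)
    for lo in range(0, n_haps, chunk):
        hi = min(lo + chunk, n_haps)
        _, p_alt = _forward_backward_batch(haps[lo:hi], ph, positions, p)
        block = haps[lo:hi].copy()
        miss = block == HAP_MISSING
        block[miss] = (p_alt[miss] > p.posterior_threshold).astype(block.dtype)
        imputed[lo:hi] = block

    N = target.n_samples
    newly = target.missing_mask()[:, covered]
    filled = np.stack([imputed[:N], imputed[N:]], axis=2).astype(out.calls.dtype)
    sub = out.calls[:, covered]
    sub[newly] = filled[newly]
    out.calls[:, covered] = sub
    psub = out.phased[:, covered]
    psub[newly] = True
    out.phased[:, covered] = psub
    return out, uncovered


def write_uniform_map(
    m: GenotypeMatrix, rate_cM_per_Mb: float, path
) -> None:
    """Write a PLINK-format genetic map with a uniform recombination rate.

    Rows are (chrom, id, cM, bp) with ``cM = bp * rate / 1e6``; strictly
    increasing in bp by construction.  Engines like Beagle accept such maps
    for sweeping uniform rates (typically 0.5–2 cM/Mb).
    """
    if rate_cM_per_Mb <= 0:
        raise ValidationError("map rate must be positive")
    with open(str(path), "w") as fh:
        for pos in m.positions:
            cm = pos * rate_cM_per_Mb / 1e6
            fh.write(f"{m.chrom}\t{m.chrom}:{pos}\t{cm:.8f}\t{pos}\n")


def beagle_adapter(
    target_vcf,
    panel_vcf,
    workdir,
    jar_path=None,
    map_path=None,
    map_rate: float | None = None,
    java: str = "java",
    runner=None,
) -> Path:
    """Stage inputs and invoke an external Beagle-style imputation jar.

    Optional feature: the jar is never bundled.  ``runner`` may be any
    callable accepting an argv list (defaults to ``subprocess.run``), which
    also allows harness testing with a stub.  The exact command line is
    written to ``workdir/beagle.cmd`` before execution.

    Raises
    ------
    ValidationError
        If no jar is supplied — supply one via ``jar_path`` (CLI flag
        ``--beagle-jar``).
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if jar_path is None or not Path(jar_path).exists():
        raise ValidationError(
            "external imputation engine not found: this is an optional "
            "dependency; supply the jar with --beagle-jar"
        )
    if map_path is None and map_rate is not None:
        from chimpanel.vcfio import read_vcf

        chrom = _first_chrom(target_vcf)
        tm = read_vcf(target_vcf, chrom)
        map_path = workdir / "uniform.map"
        write_uniform_map(tm, map_rate, map_path)

    out_prefix = workdir / "imputed"
    argv = [
        java,
        "-jar",
        str(jar_path),
        f"gt={target_vcf}",
        f"ref={panel_vcf}",
        f"out={out_prefix}",
    ]
    if map_path is not None:
        argv.append(f"map={map_path}")
    (workdir / "beagle.cmd").write_text(" ".join(argv) + "\n")
    run = runner if runner is not None else (
        lambda a: subprocess.run(a, check=True)
    )
    run(argv)
    out_vcf = Path(str(out_prefix) + ".vcf.gz")
    if not out_vcf.exists():
        out_vcf = Path(str(out_prefix) + ".vcf")
    return out_vcf


def _first_chrom(vcf_path) -> str:
    from cyvcf2 import VCF

    v = VCF(str(vcf_path))
    for rec in v:
        v.close()
        return rec.CHROM
    v.close()
    raise ValidationError(f"empty VCF: {vcf_path}")
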