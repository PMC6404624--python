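"""Synthetic allopolyploid inbred populations with known variance structure.

The generator emulates, at desk scale, a multi-environment trial of fully
inbred lines from an allopolyploid genome: chromosomes come in homeolog
groups replicated across subgenomes, each split by a centromere into a
short and a long arm; GBS-like marker positions are depleted inside the
centromere (mimicking methylation-driven marker loss, the signal the
centromere locator exploits); genotypes are homozygous 0/2 mosaics of a
small founder panel (a simple copying process that induces weak within-
chromosome LD); and phenotypes are built generatively from the same kernel
machinery the scan fits: background additive and additive-by-additive
effects, per-arm additive effects, optional arm-pair interaction effects,
fixed environment effects, and i.i.d. residuals, in an unbalanced design.

Every drawn effect vector and its realized variance are recorded in a truth
record so recovery can be checked against what was actually simulated, not
just the targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    CentromereTable,
    GenotypeMatrix,
    MarkerMap,
    assign_arms,
    arm_marker_sets,
    write_genotype_vcf,
)
from .kinship import KinshipMatrix, additive_kinship, epistatic_kernel

__all__ = [
    "SimConfig",
    "SimOutput",
    "realized_scale",
    "simulate_genome",
    "simulate_phenotypes",
    "simulate",
    "write_output",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic population.

    Defaults describe the desk-scale standard scenario used throughout the
    test-suite: a single homeolog group across three subgenomes (six
    chromosome arms), 400 inbred lines and three environments in an
    unbalanced design — a scaled-down analogue of a multi-environment wheat
    breeding trial.
    """

    n_lines: int = 400
    homeolog_groups: int = 1
    subgenomes: tuple[str, ...] = ("A", "B", "D")
    chromosome_length: int = 600_000_000
    markers_per_arm: int = 250
    centromere_fraction: float = 0.10
    depletion_factor: float = 0.9    # fraction of marker density lost inside the centromere
    n_founders: int = 6              # narrow elite pool: strong, arm-specific relatedness
    n_parents: int = 40              # breeding parents drawn as founder mosaics
    family_size: int = 1             # inbred sibs per biparental cross (1 = no family structure)
    switch_prob: float = 0.02        # haplotype-switch probability between adjacent markers
    maf_range: tuple[float, float] = (0.1, 0.9)
    het_rate: float = 0.0
    missing_rate: float = 0.0
    n_environments: int = 3
    obs_prob: float = 0.9            # per-line inclusion probability per environment
    env_sd: float = 1.0
    mu: float = 0.0
    background_additive_var: float = 0.15
    background_epistatic_var: float = 0.05
    arm_additive_var: float | dict = 0.10
    interactions: tuple = ()         # (arm_i, arm_j, variance, mode) tuples
    residual_var: float = 1.0
    background_excludes: tuple[str, ...] = ()  # arms left out of the generative background
    seed: int = 0
    omit_centromere_for: tuple[str, ...] = ()

    def arm_var(self, arm: str) -> float:
        if isinstance(self.arm_additive_var, dict):
            return float(self.arm_additive_var.get(arm, 0.0))
        return float(self.arm_additive_var)

    def validate(self) -> None:
        if not (0.0 < self.centromere_fraction < 1.0):
            raise ValueError("centromere fraction must lie strictly between 0 and 1")
        if self.markers_per_arm < 2:
            raise ValueError("need at least 2 markers per arm")
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        if not (0.0 <= self.depletion_factor <= 1.0):
            raise ValueError("depletion factor must be in [0, 1]")
        for v in (
            self.background_additive_var,
            self.background_epistatic_var,
            self.residual_var,
        ):
            if v < 0:
                raise ValueError("variances must be nonnegative")
        cen_len = self.centromere_fraction * self.chromosome_length
        if cen_len >= self.chromosome_length:
            raise ValueError("centromere wider than the chromosome")


@dataclass
class SimOutput:
    geno: GenotypeMatrix
    marker_map: MarkerMap
    centromeres: CentromereTable
    pheno: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _chromosome_names(cfg: SimConfig) -> list[str]:
    return [f"{g}{s}" for g in range(1, cfg.homeolog_groups + 1) for s in cfg.subgenomes]


def _mosaic(pool: np.ndarray, n_out: int, region: np.ndarray, switch_prob: float,
            rng: np.random.Generator) -> np.ndarray:
    """Haplotypes built by copying along a pool with Markov switching.

    The copied-source index restarts at region boundaries (arm S / centromere
    / arm L) so linkage does not persist across the centromere.
    """
    n_pool, n_mark = pool.shape
    idx = np.empty((n_out, n_mark), dtype=int)
    idx[:, 0] = rng.integers(0, n_pool, size=n_out)
    switches = rng.random((n_out, n_mark - 1)) < switch_prob
    new_draws = rng.integers(0, n_pool, size=(n_out, n_mark - 1))
    for j in range(1, n_mark):
        if region[j] != region[j - 1]:
            idx[:, j] = rng.integers(0, n_pool, size=n_out)
        else:
            idx[:, j] = np.where(switches[:, j - 1], new_draws[:, j - 1], idx[:, j - 1])
    return pool[idx, np.arange(n_mark)[None, :]]


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Marker map, centromere table and inbred genotypes for one population.

    With ``family_size > 1`` the population is family-structured like a
    breeding program: parents are founder mosaics, each biparental cross
    yields ``family_size`` fully inbred sib lines recombining between the two
    parent haplotypes.  This produces the strong within-family relatedness
    typical of line breeding panels.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    L = cfg.chromosome_length
    cen_start = int(round(L * (0.5 - cfg.centromere_fraction / 2.0)))
    cen_end = int(round(L * (0.5 + cfg.centromere_fraction / 2.0)))

    # pedigree shared across chromosomes
    family_structured = cfg.family_size > 1
    if family_structured:
        n_families = int(np.ceil(cfg.n_lines / cfg.family_size))
        fam_parents = np.array(
            [rng.choice(cfg.n_parents, size=2, replace=False) for _ in range(n_families)]
        )
        line_family = np.repeat(np.arange(n_families), cfg.family_size)[: cfg.n_lines]

    map_rows, cent_rows = [], []
    all_markers: list[str] = []
    hap_cols: list[np.ndarray] = []
    target_freqs: dict[str, float] = {}
    lo_f, hi_f = cfg.maf_range
    for chrom in _chromosome_names(cfg):
        # arm positions uniform on each arm; centromeric markers at the
        # depleted density so the dip is visible but not an empty gap
        n_arm = cfg.markers_per_arm
        arm_len = cen_start - 1
        n_cen = int(round((1.0 - cfg.depletion_factor) * n_arm * (cen_end - cen_start) / max(arm_len, 1)))
        pos_s = rng.integers(1, cen_start, size=n_arm)
        pos_l = rng.integers(cen_end + 1, L + 1, size=n_arm)
        pos_c = rng.integers(cen_start, cen_end + 1, size=n_cen)
        positions = np.sort(np.concatenate([pos_s, pos_c, pos_l]))
        names = [f"{chrom}_m{k:05d}" for k in range(positions.size)]
        for name, p in zip(names, positions):
            map_rows.append({"marker_id": name, "chromosome": chrom, "position": int(p)})
        all_markers.extend(names)
        cent_rows.append({"chromosome": chrom, "start": cen_start, "end": cen_end, "source": "annotated"})

        n_mark = positions.size
        p_target = rng.uniform(lo_f, hi_f, size=n_mark)
        target_freqs.update(zip(names, p_target))
        founders = (rng.random((cfg.n_founders, n_mark)) < p_target).astype(float)
        region = np.where(positions < cen_start, 0, np.where(positions > cen_end, 2, 1))
        if family_structured:
            parents = _mosaic(founders, cfg.n_parents, region, cfg.switch_prob, rng)
            hap = np.empty((cfg.n_lines, n_mark))
            for fam in range(n_families):
                members = np.nonzero(line_family == fam)[0]
                if members.size == 0:
                    continue
                pair = parents[fam_parents[fam]]
                hap[members] = _mosaic(pair, members.size, region, cfg.switch_prob, rng)
        else:
            hap = _mosaic(founders, cfg.n_lines, region, cfg.switch_prob, rng)
        hap_cols.append(hap)

    calls = 2.0 * np.concatenate(hap_cols, axis=1)
    if cfg.het_rate > 0:
        het = rng.random(calls.shape) < cfg.het_rate
        calls[het] = 1.0
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = np.nan

    lines = [f"L{k:04d}" for k in range(cfg.n_lines)]
    geno = GenotypeMatrix(lines=lines, markers=all_markers, calls=calls)
    marker_map = MarkerMap(pd.DataFrame(map_rows))
    # generative metadata (not part of the map contract): target frequencies
    marker_map.table.attrs["target_freq"] = target_freqs
    centromeres = CentromereTable(pd.DataFrame(cent_rows))
    return marker_map, centromeres, geno


def realized_scale(K: KinshipMatrix, sigma2: float) -> float:
    """Approximate line-scale variance contributed by g ~ N(0, sigma2 K).

    Var(g_i) ~= sigma2 * mean(diag K); on fully inbred lines the additive
    kinship diagonal averages about 2 and its Hadamard square about 4, so a
    component-scale sigma2 contributes roughly 2x (4x) that much phenotypic
    variance.  Proportions of genetic variance (h2) are computed on the
    component scale throughout, matching the mixed-model accounting.
    """
    return sigma2 * float(np.mean(np.diag(K.values)))


def _draw_from_kernel(K: KinshipMatrix, sigma2: float, rng: np.random.Generator) -> np.ndarray:
    """One draw g ~ N(0, sigma2 K); exact zeros when the variance is zero."""
    if sigma2 == 0.0:
        return np.zeros(K.n_lines)
    w, U = K.eigh()
    w = np.clip(w, 0.0, None)
    return U @ (np.sqrt(sigma2 * w) * rng.standard_normal(K.n_lines))


def simulate_phenotypes(
    marker_map: MarkerMap,
    centromeres: CentromereTable,
    geno: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    kernel_cache: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Unbalanced multi-environment phenotypes generated from kernel-normal effects.

    ``kernel_cache`` (an ordinary dict) lets repeated phenotype draws on the
    same genome reuse the kernels and their eigendecompositions.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    cache = kernel_cache if kernel_cache is not None else {}
    if "assignment" not in cache:
        cache["assignment"] = assign_arms(marker_map, centromeres)
    assignment = cache["assignment"]
    arm_sets = arm_marker_sets(assignment)
    if "arms" not in cache:
        cache["arms"] = {arm: additive_kinship(geno, m, label=arm) for arm, m in arm_sets.items()}
    arm_kernels = cache["arms"]
    bg_key = ("bg", tuple(sorted(cfg.background_excludes)))
    if bg_key not in cache:
        bg_markers = [
            m for arm, ms in arm_sets.items() if arm not in set(cfg.background_excludes)
            for m in ms
        ]
        k_bg = additive_kinship(geno, bg_markers, label="background")
        cache[bg_key] = (k_bg, epistatic_kernel([k_bg, k_bg]))
    k_bg, k_bg_epi = cache[bg_key]

    effects: dict[str, np.ndarray] = {}
    sigma2_params: dict[str, float] = {}
    effects["bgA"] = _draw_from_kernel(k_bg, cfg.background_additive_var, rng)
    sigma2_params["bgA"] = cfg.background_additive_var
    effects["bgI"] = _draw_from_kernel(k_bg_epi, cfg.background_epistatic_var, rng)
    sigma2_params["bgI"] = cfg.background_epistatic_var
    for arm in sorted(arm_kernels):
        effects[f"A:{arm}"] = _draw_from_kernel(arm_kernels[arm], cfg.arm_var(arm), rng)
        sigma2_params[f"A:{arm}"] = cfg.arm_var(arm)

    for spec in cfg.interactions:
        arm_i, arm_j, var, mode = spec
        arm_i, arm_j = sorted((arm_i, arm_j))
        int_key = ("int", arm_i, arm_j)
        if int_key not in cache:
            cache[int_key] = epistatic_kernel([arm_kernels[arm_i], arm_kernels[arm_j]])
        k_int = cache[int_key]
        name = f"AxA:{arm_i}:{arm_j}"
        if mode == "independent":
            effects[name] = _draw_from_kernel(k_int, var, rng)
        elif mode in ("positive_product", "negative_product"):
            base = effects[f"A:{arm_i}"] * effects[f"A:{arm_j}"]
            v = float(np.var(base))
            if v == 0.0 or var == 0.0:
                effects[name] = np.zeros(geno.n_lines)
            else:
                lam = np.sqrt(realized_scale(k_int, var) / v)
                effects[name] = (lam if mode == "positive_product" else -lam) * base
        else:
            raise ValueError(f"unknown interaction mode {mode!r}")
        sigma2_params[name] = var

    total_g = np.sum(list(effects.values()), axis=0)
    env_ids = [f"E{k:02d}" for k in range(cfg.n_environments)]
    env_effects = rng.normal(0.0, cfg.env_sd, size=cfg.n_environments)

    include = rng.random((geno.n_lines, cfg.n_environments)) < cfg.obs_prob
    empty = ~include.any(axis=1)
    if empty.any():  # every line is phenotyped at least once
        include[np.nonzero(empty)[0], rng.integers(0, cfg.n_environments, size=int(empty.sum()))] = True

    rows = []
    for i, line in enumerate(geno.lines):
        for e in range(cfg.n_environments):
            if include[i, e]:
                value = (
                    cfg.mu
                    + env_effects[e]
                    + total_g[i]
                    + rng.normal(0.0, np.sqrt(cfg.residual_var))
                )
                rows.append({"line_id": line, "env_id": env_ids[e], "value": value})
    pheno = pd.DataFrame(rows)

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "env_effects": {e: float(v) for e, v in zip(env_ids, env_effects)},
        "effects": {k: v.tolist() for k, v in effects.items()},
        "sigma2_params": sigma2_params,
        "realized_variances": {k: float(np.var(v)) for k, v in effects.items()},
        "n_observations": len(rows),
    }
    return pheno, truth


def simulate(cfg: SimConfig) -> SimOutput:
    """Full generative run: genome, genotypes and phenotypes from one seed."""
    rng = np.random.default_rng(cfg.seed)
    marker_map, centromeres, geno = simulate_genome(cfg, rng)
    pheno, truth = simulate_phenotypes(marker_map, centromeres, geno, cfg, rng)
    if cfg.omit_centromere_for:
        keep = ~centromeres.table["chromosome"].isin(cfg.omit_centromere_for)
        centromeres = CentromereTable(centromeres.table[keep].reset_index(drop=True))
    return SimOutput(geno=geno, marker_map=marker_map, centromeres=centromeres, pheno=pheno, truth=truth)


def write_output(out_dir, sim: SimOutput) -> None:
    """Persist a simulated dataset as VCF + headered TSVs + a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_vcf(out / "genotypes.vcf", sim.geno, sim.marker_map)
    sim.marker_map.table.to_csv(out / "map.tsv", sep="\t", index=False)
    sim.centromeres.table.to_csv(out / "centromeres.tsv", sep="\t", index=False)
    sim.pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(sim.truth))
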