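"""Arm-pair and homeolog-triplet epistasis scans via nested mixed models.

For every chromosome-arm pair (i, i') three nested models are fitted on
identical data:

  model 1:  background additive + background epistatic terms only;
  model 2:  model 1 + the two arm additive terms  g_Ai, g_Ai';
  model 3:  model 2 + the arm interaction term    g_Ai x Ai'  with
            covariance K_i (Hadamard) K_i'.

Sequential likelihood ratio tests compare 2 vs 1 (additive, df = 2) and
3 vs 2 (interaction, df = 1) with D = 2 (logL_alt - logL_null) clamped at 0
referred to the chi-square upper tail; a test whose component is estimated
on the boundary (exactly zero) is reported with p = 1, which makes the scan
conservative.  Component h2 values are each genetic variance divided by the
total genetic variance of the fullest model.  For the homeologous triplets,
a model with all three two-way interactions (model 4) is compared against
one adding the three-way Hadamard kernel (model 5, df = 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import effects as effects_mod
from .genome_model import (
    CentromereTable,
    GenotypeMatrix,
    MarkerMap,
    arm_marker_sets,
    assign_arms,
    classify_pair,
    parse_arm_label,
)
from .kinship import KinshipMatrix, additive_kinship, epistatic_kernel
from .reml import FitOptions, MixedModelFit, ModelSpec, build_design, fit

__all__ = [
    "LRTResult",
    "PairTestRecord",
    "TripletTestRecord",
    "ScanData",
    "lrt",
    "bonferroni",
    "test_pair",
    "test_triplet",
    "run_scan",
    "run_triplet_scan",
]

logger = logging.getLogger(__name__)


@dataclass
class LRTResult:
    D: float
    df: int
    p: float
    boundary: bool = False


def lrt(logl_null: float, logl_alt: float, df: int, boundary: bool = False) -> LRTResult:
    """Likelihood ratio test of nested REML fits with boundary handling.

    D = max(0, 2 (logL_alt - logL_null)) referred to chi2_df; when the tested
    component was estimated on the boundary (zero) the p-value is 1.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    D = max(0.0, 2.0 * (logl_alt - logl_null))
    p = 1.0 if boundary else float(stats.chi2.sf(D, df))
    if D == 0.0:
        p = 1.0
    return LRTResult(D=D, df=df, p=p, boundary=boundary)


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


# ---------------------------------------------------------------------------
# scan data: inputs plus kernel caches shared across pairs
# ---------------------------------------------------------------------------

@dataclass
class ScanData:
    geno: GenotypeMatrix
    assignment: pd.DataFrame
    pheno: pd.DataFrame
    trait: str = "trait"
    _design: tuple | None = field(default=None, repr=False)
    _arm_kernels: dict = field(default_factory=dict, repr=False)
    _backgrounds: dict = field(default_factory=dict, repr=False)
    _arm_parts: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_tables(
        cls,
        geno: GenotypeMatrix,
        marker_map: MarkerMap,
        centromeres: CentromereTable,
        pheno: pd.DataFrame,
        trait: str = "trait",
    ) -> "ScanData":
        assignment = assign_arms(marker_map, centromeres)
        return cls(geno=geno, assignment=assignment, pheno=pheno, trait=trait)

    @property
    def arms(self) -> list[str]:
        return sorted(arm_marker_sets(self.assignment))

    def design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._design is None:
            self._design = build_design(self.pheno, self.geno.lines)
        return self._design

    def arm_kernel(self, arm: str) -> KinshipMatrix:
        if arm not in self._arm_kernels:
            markers = arm_marker_sets(self.assignment)[arm]
            self._arm_kernels[arm] = additive_kinship(self.geno, markers, label=arm)
        return self._arm_kernels[arm]

    def background(self, excluded: Iterable[str]) -> tuple[KinshipMatrix, KinshipMatrix]:
        """Leave-arms-out background kernels, assembled from cached per-arm
        cross-product numerators (equivalent to recomputing on the marker
        complement, since imputation and allele frequencies are per marker)."""
        key = frozenset(excluded)
        if key not in self._backgrounds:
            if "num" not in self._arm_parts:
                parts_n, parts_d = {}, {}
                for arm in self.arms:
                    k = self.arm_kernel(arm)
                    d = k.provenance["denominator"]
                    parts_n[arm] = k.values * d
                    parts_d[arm] = d
                self._arm_parts["num"], self._arm_parts["den"] = parts_n, parts_d
            keep = [a for a in self.arms if a not in key]
            if not keep:
                raise ValueError(f"excluding arms {sorted(key)} leaves no markers")
            den = sum(self._arm_parts["den"][a] for a in keep)
            num = sum(self._arm_parts["num"][a] for a in keep)
            label = "background" + ("-minus-" + "+".join(sorted(key)) if key else "")
            k_add = KinshipMatrix(
                tuple(self.geno.lines), num / den,
                provenance={"kind": "additive", "label": label, "denominator": den},
            )
            k_epi = epistatic_kernel([k_add, k_add])
            k_epi.provenance["label"] = label + "-epistatic"
            self._backgrounds[key] = (k_add, k_epi)
        return self._backgrounds[key]

    def model(self, kernels: dict[str, KinshipMatrix]) -> ModelSpec:
        y, X, line_index = self.design()
        return ModelSpec(y=y, X=X, line_index=line_index, line_ids=tuple(self.geno.lines), kernels=kernels)


def _warm(opts: FitOptions | None, prev: MixedModelFit | None) -> FitOptions:
    base = opts or FitOptions()
    init = dict(prev.variance_components) if prev is not None else None
    return FitOptions(
        max_iter=base.max_iter,
        tol=base.tol,
        use_ai=base.use_ai,
        n_em_start=base.n_em_start,
        boundary_eps=base.boundary_eps,
        floor=base.floor,
        init=init,
    )


def _h2_table(fit_result: MixedModelFit) -> dict[str, float]:
    """Each genetic component over the total genetic variance of the fit."""
    genetic = {k: v for k, v in fit_result.variance_components.items() if k != "residual"}
    total = sum(genetic.values())
    if total <= 0:
        return {k: 0.0 for k in genetic}
    return {k: v / total for k, v in genetic.items()}


# ---------------------------------------------------------------------------
# pair tests
# ---------------------------------------------------------------------------

@dataclass
class PairTestRecord:
    trait: str
    arm_i: str
    arm_j: str
    pair_class: str
    logREML: dict[str, float]            # model1/model2/model3
    components: dict[str, float]         # model 3 variance components
    additive_lrt: LRTResult
    interaction_lrt: LRTResult
    h2: dict[str, float]
    rho: effects_mod.CorrelationResult | None
    converged: bool
    error: str | None = None
    sig_nominal: bool | None = None
    sig_bonferroni: bool | None = None

    def to_row(self) -> dict:
        row = {
            "trait": self.trait,
            "arm_i": self.arm_i,
            "arm_j": self.arm_j,
            "class": self.pair_class,
            "logREML_m1": self.logREML.get("model1", np.nan),
            "logREML_m2": self.logREML.get("model2", np.nan),
            "logREML_m3": self.logREML.get("model3", np.nan),
            "D_additive": self.additive_lrt.D,
            "p_additive": self.additive_lrt.p,
            "D_interaction": self.interaction_lrt.D,
            "p_interaction": self.interaction_lrt.p,
            "var_bgA": self.components.get("bgA", np.nan),
            "var_bgI": self.components.get("bgI", np.nan),
            "var_arm_i": self.components.get(f"A:{self.arm_i}", np.nan),
            "var_arm_j": self.components.get(f"A:{self.arm_j}", np.nan),
            "var_interaction": self.components.get(f"AxA:{self.arm_i}:{self.arm_j}", np.nan),
            "var_residual": self.components.get("residual", np.nan),
            "h2_arm_i": self.h2.get(f"A:{self.arm_i}", np.nan),
            "h2_arm_j": self.h2.get(f"A:{self.arm_j}", np.nan),
            "h2_interaction": self.h2.get(f"AxA:{self.arm_i}:{self.arm_j}", np.nan),
            "rho": self.rho.rho if self.rho else np.nan,
            "rho_p": self.rho.p if self.rho else np.nan,
            "rho_mode": self.rho.mode if self.rho else "",
            "converged": self.converged,
            "error": self.error or "",
            "significant_nominal": self.sig_nominal,
            "significant_bonferroni": self.sig_bonferroni,
        }
        return row


def test_pair(
    data: ScanData,
    arm_i: str,
    arm_j: str,
    opts: FitOptions | None = None,
) -> PairTestRecord:
    """Fit models 1-3 for one arm pair and assemble the sequential LRTs."""
    k_i = data.arm_kernel(arm_i)
    k_j = data.arm_kernel(arm_j)
    k_int = epistatic_kernel([k_i, k_j])
    bg_a, bg_i = data.background({arm_i, arm_j})
    int_name = f"AxA:{arm_i}:{arm_j}"

    kernels1 = {"bgA": bg_a, "bgI": bg_i}
    kernels2 = dict(kernels1, **{f"A:{arm_i}": k_i, f"A:{arm_j}": k_j})
    kernels3 = dict(kernels2, **{int_name: k_int})

    fit1 = fit(data.model(kernels1), _warm(opts, None) if opts else opts)
    fit2 = fit(data.model(kernels2), _warm(opts, fit1))
    fit3 = fit(data.model(kernels3), _warm(opts, fit2))

    add_boundary = fit2.boundary_flags[f"A:{arm_i}"] and fit2.boundary_flags[f"A:{arm_j}"]
    int_boundary = fit3.boundary_flags[int_name]
    additive = lrt(fit1.logREML, fit2.logREML, df=2, boundary=add_boundary)
    interaction = lrt(fit2.logREML, fit3.logREML, df=1, boundary=int_boundary)

    rho = None
    if not int_boundary:
        rho = effects_mod.additive_interaction_correlation(fit3, arm_i, arm_j, interaction=int_name)

    try:
        pair_class = classify_pair(parse_arm_label(arm_i), parse_arm_label(arm_j))
    except ValueError:
        pair_class = "unclassified"

    return PairTestRecord(
        trait=data.trait,
        arm_i=arm_i,
        arm_j=arm_j,
        pair_class=pair_class,
        logREML={"model1": fit1.logREML, "model2": fit2.logREML, "model3": fit3.logREML},
        components=dict(fit3.variance_components),
        additive_lrt=additive,
        interaction_lrt=interaction,
        h2=_h2_table(fit3),
        rho=rho,
        converged=fit1.converged and fit2.converged and fit3.converged,
    )


# ---------------------------------------------------------------------------
# triplet tests
# ---------------------------------------------------------------------------

@dataclass
class TripletTestRecord:
    trait: str
    arms: tuple[str, str, str]
    threeway_lrt: LRTResult
    logREML: dict[str, float]
    components: dict[str, float]   # model 5 variance components
    h2: dict[str, float]
    converged: bool
    error: str | None = None

    def to_row(self) -> dict:
        a, b, c = self.arms
        return {
            "trait": self.trait,
            "arm_i": a,
            "arm_j": b,
            "arm_k": c,
            "logREML_m4": self.logREML.get("model4", np.nan),
            "logREML_m5": self.logREML.get("model5", np.nan),
            "D_threeway": self.threeway_lrt.D,
            "p_threeway": self.threeway_lrt.p,
            "var_threeway": self.components.get(f"AxAxA:{a}:{b}:{c}", np.nan),
            "h2_threeway": self.h2.get(f"AxAxA:{a}:{b}:{c}", np.nan),
            "converged": self.converged,
            "error": self.error or "",
        }


def test_triplet(
    data: ScanData,
    arms: Sequence[str],
    opts: FitOptions | None = None,
) -> TripletTestRecord:
    """Model 4 (all two-way terms) vs model 5 (+ three-way Hadamard kernel)."""
    a, b, c = sorted(arms)
    ks = {arm: data.arm_kernel(arm) for arm in (a, b, c)}
    bg_a, bg_i = data.background({a, b, c})
    kernels4: dict[str, KinshipMatrix] = {"bgA": bg_a, "bgI": bg_i}
    for arm in (a, b, c):
        kernels4[f"A:{arm}"] = ks[arm]
    for x, y_ in ((a, b), (a, c), (b, c)):
        kernels4[f"AxA:{x}:{y_}"] = epistatic_kernel([ks[x], ks[y_]])
    three_name = f"AxAxA:{a}:{b}:{c}"
    kernels5 = dict(kernels4, **{three_name: epistatic_kernel([ks[a], ks[b], ks[c]])})

    fit4 = fit(data.model(kernels4), opts)
    fit5 = fit(data.model(kernels5), _warm(opts, fit4))
    res = lrt(fit4.logREML, fit5.logREML, df=1, boundary=fit5.boundary_flags[three_name])
    return TripletTestRecord(
        trait=data.trait,
        arms=(a, b, c),
        threeway_lrt=res,
        logREML={"model4": fit4.logREML, "model5": fit5.logREML},
        components=dict(fit5.variance_components),
        h2=_h2_table(fit5),
        converged=fit4.converged and fit5.converged,
    )


# ---------------------------------------------------------------------------
# scan orchestration
# ---------------------------------------------------------------------------

def _failed_pair_record(data: ScanData, arm_i: str, arm_j: str, err: Exception) -> PairTestRecord:
    failed = LRTResult(D=0.0, df=1, p=1.0, boundary=True)
    try:
        pair_class = classify_pair(parse_arm_label(arm_i), parse_arm_label(arm_j))
    except ValueError:
        pair_class = "unclassified"
    return PairTestRecord(
        trait=data.trait,
        arm_i=arm_i,
        arm_j=arm_j,
        pair_class=pair_class,
        logREML={},
        components={},
        additive_lrt=LRTResult(D=0.0, df=2, p=1.0, boundary=True),
        interaction_lrt=failed,
        h2={},
        rho=None,
        converged=False,
        error=f"{type(err).__name__}: {err}",
    )


def run_scan(
    data: ScanData,
    pairs: Sequence[tuple[str, str]],
    opts: FitOptions | None = None,
    alpha: float = 0.05,
    cache_dir=None,
) -> pd.DataFrame:
    """Run the pair scan over a fixed pair list; one row per pair.

    Pairs are processed in deterministic (sorted) order; a failure in one
    pair is recorded and does not abort the scan.  The Bonferroni level uses
    the number of pairs attempted.  With ``cache_dir`` set, per-pair results
    are cached as JSON and reused on rerun.
    """
    pairs = sorted((min(a, b), max(a, b)) for a, b in pairs)
    threshold = bonferroni(alpha, len(pairs))
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    rows = []
    for idx, (a, b) in enumerate(pairs):
        cache_file = cache / f"{data.trait}_{a}_{b}.json" if cache is not None else None
        if cache_file is not None and cache_file.exists():
            row = json.loads(cache_file.read_text())
        else:
            try:
                rec = test_pair(data, a, b, opts)
            except Exception as err:  # noqa: BLE001 - one pair must not kill the scan
                logger.warning("pair %s/%s failed: %s", a, b, err)
                rec = _failed_pair_record(data, a, b, err)
            rec.sig_nominal = rec.interaction_lrt.p < alpha
            rec.sig_bonferroni = rec.interaction_lrt.p < threshold
            row = rec.to_row()
            if cache_file is not None:
                cache_file.write_text(json.dumps(row, default=float))
        rows.append(row)
        logger.info("pair %d/%d %s/%s p_int=%.3g", idx + 1, len(pairs), a, b, row["p_interaction"])
    return pd.DataFrame(rows)


def run_triplet_scan(
    data: ScanData,
    triplets: Sequence[Sequence[str]],
    opts: FitOptions | None = None,
) -> pd.DataFrame:
    """Run the three-way scan over a fixed triplet list; one row per triplet."""
    triplets = sorted(tuple(sorted(t)) for t in triplets)
    rows = []
    for t in triplets:
        try:
            rec = test_triplet(data, t, opts)
            rows.append(rec.to_row())
        except Exception as err:  # noqa: BLE001
            logger.warning("triplet %s failed: %s", t, err)
            rows.append(
                {
                    "trait": data.trait,
                    "arm_i": t[0],
                    "arm_j": t[1],
                    "arm_k": t[2],
                    "logREML_m4": np.nan,
                    "logREML_m5": np.nan,
                    "D_threeway": 0.0,
                    "p_threeway": 1.0,
                    "var_threeway": np.nan,
                    "h2_threeway": np.nan,
                    "converged": False,
                    "error": f"{type(err).__name__}: {err}",
                }
            )
    return pd.DataFrame(rows)
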