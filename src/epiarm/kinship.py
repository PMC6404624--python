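"""Genomic relationship matrices and Hadamard epistatic kernels.

Additive kinship follows the classic allele-frequency-scaled cross-product:
with dosage column g_j centered at 2*p_j (p_j the counted-allele frequency
among the analyzed lines) the matrix is K = W W' / (2 * sum_j p_j (1-p_j)).
Missing calls are mean-imputed per marker before centering; monomorphic
markers carry no relationship information and are dropped with a warning.

Additive-by-additive epistatic covariance between two disjoint marker
regions is the elementwise (Hadamard) product of their additive kinships,
K_ij = K_i * K_j; the three-way kernel multiplies three factors.  By the
Schur product theorem these products stay positive semidefinite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_model import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "additive_kinship",
    "epistatic_kernel",
    "background_kernels",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


@dataclass
class KinshipMatrix:
    """Symmetric line-by-line covariance with provenance of its construction."""

    line_ids: tuple[str, ...]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)
    _rank: int | None = field(default=None, repr=False, compare=False)
    _eigh: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.line_ids = tuple(self.line_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kinship shape {self.values.shape} != ({n}, {n})")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"kinship not symmetric (max asymmetry {asym:.2e})")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def eigh(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (ascending eigenvalues, eigenvectors)."""
        if self._eigh is None:
            w, U = np.linalg.eigh(self.values)
            self._eigh = (w, U)
        return self._eigh

    def min_eigenvalue(self) -> float:
        return float(self.eigh()[0][0])

    def rank(self, tol: float | None = None) -> int:
        """Numerical rank (cached); used by rank-aware EM variance updates."""
        if self._rank is None or tol is not None:
            w = self.eigh()[0]
            cut = (tol if tol is not None else 1e-9) * max(w[-1], 1.0)
            r = int(np.sum(w > cut))
            if tol is None:
                self._rank = r
            return r
        return self._rank

    def rescaled(self) -> "KinshipMatrix":
        """Optional mean-diagonal-1 rescale (off by default everywhere)."""
        scale = float(np.mean(np.diag(self.values)))
        prov = dict(self.provenance, rescaled=True)
        return KinshipMatrix(self.line_ids, self.values / scale, prov)

    def to_tsv(self, path) -> None:
        path = Path(path)
        pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids).to_csv(
            path, sep="\t"
        )
        meta = dict(self.provenance)
        meta["n_lines"] = self.n_lines
        meta["trace"] = float(np.trace(self.values))
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        prov = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        prov.pop("n_lines", None)
        prov.pop("trace", None)
        return cls(tuple(str(i) for i in df.index), df.to_numpy(), prov)


def _centered_dosages(
    geno: GenotypeMatrix, marker_ids: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Mean-imputed, 2p-centered dosage columns; monomorphic markers dropped."""
    if marker_ids is None:
        marker_ids = list(geno.markers)
    idx = geno.marker_index(marker_ids)
    if idx.size == 0:
        raise ValueError("empty marker subset")
    calls = geno.calls[:, idx].copy()
    means = np.nanmean(calls, axis=0)
    nan_mask = ~np.isfinite(calls)
    if nan_mask.any():
        calls[nan_mask] = np.broadcast_to(means, calls.shape)[nan_mask]
    p = means / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers in the subset are monomorphic")
    if (~poly).sum():
        dropped = [m for m, keep in zip(marker_ids, poly) if not keep]
        logger.warning("dropping %d monomorphic markers (e.g. %s)", len(dropped), dropped[:3])
    W = calls[:, poly] - 2.0 * p[poly]
    return W, p[poly], [m for m, keep in zip(marker_ids, poly) if keep]


def additive_kinship(
    geno: GenotypeMatrix,
    marker_ids: Sequence[str] | None = None,
    label: str = "genome",
) -> KinshipMatrix:
    """Allele-frequency-scaled additive relationship matrix for a marker subset.

    K = W W' / (2 sum_j p_j (1 - p_j)) with W the 2p-centered dosage matrix.
    Allele frequencies come from the analyzed lines themselves.
    """
    W, p, used = _centered_dosages(geno, marker_ids)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    K = (W @ W.T) / denom
    return KinshipMatrix(
        tuple(geno.lines),
        K,
        provenance={
            "kind": "additive",
            "label": label,
            "n_markers": len(used),
            "denominator": denom,
        },
    )


def epistatic_kernel(kernels: Sequence[KinshipMatrix]) -> KinshipMatrix:
    """Hadamard product of 2 or 3 additive kinships: the epistatic covariance.

    All factors must share the same line ids in the same order; no silent
    reordering is performed.
    """
    if len(kernels) not in (2, 3):
        raise ValueError(f"epistatic kernel takes 2 or 3 factors, got {len(kernels)}")
    first = kernels[0]
    for k in kernels[1:]:
        if k.line_ids != first.line_ids:
            raise ValueError("kernels have mismatched line ids or order; refusing to reorder")
    values = first.values.copy()
    for k in kernels[1:]:
        values *= k.values
    factors = [k.provenance.get("label", "?") for k in kernels]
    return KinshipMatrix(
        first.line_ids,
        values,
        provenance={"kind": "epistatic", "factors": factors, "order": len(kernels)},
    )


def background_kernels(
    geno: GenotypeMatrix,
    assignment: pd.DataFrame,
    excluded_arms: Iterable[str] = (),
) -> tuple[KinshipMatrix, KinshipMatrix]:
    """Background additive and epistatic kernels with some arms left out.

    The additive background uses every non-centromeric marker whose arm is
    not excluded; the epistatic background is its self-Hadamard product
    (genome-wide additive-by-additive covariance).
    """
    excluded = set(excluded_arms)
    keep = assignment[~assignment["in_centromere"] & ~assignment["arm"].isin(excluded)]
    markers = list(keep["marker_id"])
    if not markers:
        raise ValueError(f"excluding arms {sorted(excluded)} leaves no markers")
    label = "background" + ("-minus-" + "+".join(sorted(excluded)) if excluded else "")
    k_add = additive_kinship(geno, markers, label=label)
    k_epi = epistatic_kernel([k_add, k_add])
    k_epi.provenance["label"] = label + "-epistatic"
    return k_add, k_epi
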