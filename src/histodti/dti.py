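"""Scalar diffusion-tensor metrics and Westin shape indices.

The diffusion tensor's three eigenvalues (``lambda1 >= lambda2 >= lambda3``,
diffusivities in mm^2/s or any consistent unit) are the entry point: from
them we derive the standard rotation-invariant scalars

* MD  — mean diffusivity, ``(l1 + l2 + l3) / 3``
* AD  — axial diffusivity, ``l1``
* RD  — radial diffusivity, ``(l2 + l3) / 2``
* FA  — fractional anisotropy, normalised eigenvalue dispersion in [0, 1]

and the Westin shape indices in the trace-normalised convention

* CL = (l1 - l2) / T,  CP = 2 (l2 - l3) / T,  CS = 3 l3 / T,  T = l1+l2+l3

which partition tensor shape so that ``CL + CP + CS = 1`` exactly.  The
lambda1-normalised variant of the Westin indices is available through
``westin_norm="lambda1"`` but does not satisfy that identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EigenvalueTriple",
    "ScalarMetrics",
    "compute_scalar_metrics",
    "metrics_map",
    "METRIC_NAMES",
]

#: Output order used by :func:`metrics_map` and the CSV writers.
METRIC_NAMES = ("FA", "AD", "RD", "MD", "CL", "CP", "CS")


@dataclass(frozen=True)
class EigenvalueTriple:
    """Sorted diffusion-tensor eigenvalues, ``lambda1 >= lambda2 >= lambda3``."""

    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self) -> None:
        lam = (self.lambda1, self.lambda2, self.lambda3)
        if not all(np.isfinite(lam)):
            raise ValueError(f"eigenvalues must be finite, got {lam}")
        if not (self.lambda1 >= self.lambda2 >= self.lambda3):
            raise ValueError(f"eigenvalues must be sorted descending, got {lam}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3], dtype=float)


@dataclass(frozen=True)
class ScalarMetrics:
    """Scalar DTI metrics for one tensor (or one ROI-average tensor)."""

    FA: float
    AD: float
    RD: float
    MD: float
    CL: float
    CP: float
    CS: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_scalar_metrics(
    ev: EigenvalueTriple,
    *,
    clamp_negative: bool = False,
    westin_norm: str = "trace",
) -> ScalarMetrics:
    """Compute FA/AD/RD/MD and Westin CL/CP/CS from one eigenvalue triple.

    Parameters
    ----------
    ev
        Sorted eigenvalue triple.
    clamp_negative
        Negative eigenvalues occur in noisy tensor fits.  By default they
        are rejected with a ``ValueError`` so fit pathologies surface;
        with ``clamp_negative=True`` they are clamped to zero instead.
    westin_norm
        ``"trace"`` (default, factors 1/2/3 so CL+CP+CS = 1) or
        ``"lambda1"`` (classical l1-normalised variant).
    """
    lam = ev.as_array()
    if np.any(lam < 0):
        if not clamp_negative:
            raise ValueError(
                f"negative eigenvalues {tuple(lam)}; pass clamp_negative=True "
                "to clamp noisy fits to zero"
            )
        lam = np.clip(lam, 0.0, None)

    l1, l2, l3 = lam
    trace = l1 + l2 + l3
    if trace <= 0:
        raise ValueError("zero-trace tensor: shape indices are undefined")

    md = trace / 3.0
    ad = l1
    rd = (l2 + l3) / 2.0

    norm_sq = l1 * l1 + l2 * l2 + l3 * l3
    fa = np.sqrt(0.5) * np.sqrt(
        (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    ) / np.sqrt(norm_sq)

    if westin_norm == "trace":
        cl = (l1 - l2) / trace
        cp = 2.0 * (l2 - l3) / trace
        cs = 3.0 * l3 / trace
    elif westin_norm == "lambda1":
        cl = (l1 - l2) / l1
        cp = (l2 - l3) / l1
        cs = l3 / l1
    else:
        raise ValueError(f"unknown westin_norm {westin_norm!r}")

    return ScalarMetrics(FA=float(fa), AD=float(ad), RD=float(rd), MD=float(md),
                         CL=float(cl), CP=float(cp), CS=float(cs))


def metrics_map(
    lambda1: np.ndarray,
    lambda2: np.ndarray,
    lambda3: np.ndarray,
    *,
    mask: np.ndarray | None = None,
    clamp_negative: bool = False,
    westin_norm: str = "trace",
) -> dict[str, np.ndarray]:
    """Voxelwise scalar metrics from three aligned eigenvalue maps.

    Returns a dict of float arrays keyed by :data:`METRIC_NAMES`.  Voxels
    outside ``mask`` (or with zero trace) are emitted as NaN.
    """
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    l3 = np.asarray(lambda3, dtype=float)
    if not (l1.shape == l2.shape == l3.shape):
        raise ValueError(
            f"eigenvalue maps must share a shape, got {l1.shape}, {l2.shape}, {l3.shape}"
        )
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != l1.shape:
            raise ValueError("mask shape must match eigenvalue maps")

    if np.any((l1 < l2) | (l2 < l3)):
        bad = np.argwhere((l1 < l2) | (l2 < l3))
        raise ValueError(f"unsorted eigenvalues at {len(bad)} voxel(s), first {tuple(bad[0])}")
    neg = (l1 < 0) | (l2 < 0) | (l3 < 0)
    if np.any(neg):
        if not clamp_negative:
            raise ValueError(
                f"negative eigenvalues at {int(neg.sum())} voxel(s); "
                "pass clamp_negative=True to clamp"
            )
        l1, l2, l3 = (np.clip(a, 0.0, None) for a in (l1, l2, l3))

    trace = l1 + l2 + l3
    valid = trace > 0
    if mask is not None:
        valid &= mask

    with np.errstate(divide="ignore", invalid="ignore"):
        md = trace / 3.0
        ad = l1.copy()
        rd = (l2 + l3) / 2.0
        norm_sq = l1 * l1 + l2 * l2 + l3 * l3
        fa = np.sqrt(0.5) * np.sqrt(
            (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
        ) / np.sqrt(norm_sq)
        if westin_norm == "trace":
            cl = (l1 - l2) / trace
            cp = 2.0 * (l2 - l3) / trace
            cs = 3.0 * l3 / trace
        elif westin_norm == "lambda1":
            cl = (l1 - l2) / l1
            cp = (l2 - l3) / l1
            cs = l3 / l1
        else:
            raise ValueError(f"unknown westin_norm {westin_norm!r}")

    out = {}
    for name, arr in zip(METRIC_NAMES, (fa, ad, rd, md, cl, cp, cs)):
        arr = arr.astype(float)
        arr[~valid] = np.nan
        out[name] = arr
    return out
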