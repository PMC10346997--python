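"""Hankel/SVD motion-artifact removal (singular-spectrum subspace denoising).

The PPG window is embedded into a Hankel trajectory matrix, decomposed by
SVD, and each rank-1 component is mapped back to a time series by
anti-diagonal averaging (Hankelization).  Components whose series correlate
strongly with any accelerometer axis are motion artifacts and are removed;
the remaining components are summed to give the cleaned PPG.

For an N-sample series the embedding has L = ceil(N/2) rows and
K = N - L + 1 columns with ``H[i, j] = series[i + j]``, so the full set of
components reconstructs the series exactly (to floating-point precision).

The anti-diagonal sums of a rank-1 outer product ``u v^T`` are the linear
convolution ``u * v``; this module exploits that to produce all component
series in one batched FFT convolution instead of materializing r rank-1
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
import scipy.signal

from .config import HankelMarConfig


def build_hankel(series: Sequence[float]) -> np.ndarray:
    """Embed a series into its Hankel trajectory matrix.

    For N samples the shape is ceil(N/2) x (floor(N/2) + 1), so even
    N = 2n gives n x (n+1) and every sample through ``series[N-1]``
    appears; ``H[i, j] == series[i + j]``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"series must have at least 4 samples, got {n}")
    L = (n + 1) // 2
    return scipy.linalg.hankel(x[:L], x[L - 1:])


def hankelize(mat: np.ndarray) -> np.ndarray:
    """Map a matrix back to a series by averaging its anti-diagonals.

    Exact (not merely to rounding) for Hankel-consistent matrices: where
    an anti-diagonal is constant its value is returned directly, so
    ``hankelize(build_hankel(x)) == x`` bit for bit.
    """
    mat = np.asarray(mat, dtype=float)
    L, K = mat.shape
    n = L + K - 1
    idx = (np.arange(L)[:, None] + np.arange(K)[None, :]).ravel()
    flat = mat.ravel()
    sums = np.bincount(idx, weights=flat, minlength=n)
    out = sums / _antidiag_counts(L, K)
    lo = np.full(n, np.inf)
    hi = np.full(n, -np.inf)
    np.minimum.at(lo, idx, flat)
    np.maximum.at(hi, idx, flat)
    constant = lo == hi
    out[constant] = lo[constant]
    return out


def _antidiag_counts(L: int, K: int) -> np.ndarray:
    i = np.arange(L + K - 1)
    return np.minimum(np.minimum(i + 1, L + K - 1 - i), min(L, K))


@dataclass
class HankelSVD:
    """SVD of the Hankel embedding of one channel.

    Attributes
    ----------
    U, S, V
        Factors of ``H = U diag(S) V^T`` with ``U`` (L x r), ``S``
        non-increasing of length r = min(L, K), ``V`` (K x r).
    series
        The original samples (kept for exact-complement reconstruction).
    """

    channel_name: str
    L: int
    K: int
    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    n_samples: int
    series: np.ndarray = field(repr=False, default=None)

    @property
    def rank(self) -> int:
        return len(self.S)


def decompose(series: Sequence[float], channel_name: str = "ppg") -> HankelSVD:
    """Build the Hankel embedding of ``series`` and take its SVD."""
    x = np.asarray(series, dtype=float)
    H = build_hankel(x)
    try:
        U, S, Vt = np.linalg.svd(H, full_matrices=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"SVD failed for channel {channel_name!r}: {exc}"
        ) from exc
    return HankelSVD(channel_name=channel_name, L=H.shape[0], K=H.shape[1],
                     U=U, S=S, V=Vt.T, n_samples=len(x), series=x)


def component_series(hsvd: HankelSVD, i: int) -> np.ndarray:
    """Series of the i-th rank-1 component (anti-diagonal averaged)."""
    if not 0 <= i < hsvd.rank:
        raise IndexError(f"component {i} out of range [0, {hsvd.rank})")
    conv = np.convolve(hsvd.U[:, i], hsvd.V[:, i])
    return hsvd.S[i] * conv / _antidiag_counts(hsvd.L, hsvd.K)


def all_component_series(hsvd: HankelSVD) -> np.ndarray:
    """All component series as an (r, n_samples) array.

    Uses one batched FFT convolution over the singular-vector pairs.
    """
    conv = scipy.signal.fftconvolve(hsvd.U.T, hsvd.V.T, axes=1)
    return hsvd.S[:, None] * conv / _antidiag_counts(hsvd.L, hsvd.K)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation.

    Defined as 0 when either input has zero variance (the degenerate case;
    a flat accelerometer carries no motion information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must be equal-length with at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.clip(xc @ yc / (sx * sy), -1.0, 1.0))


@dataclass
class ComponentSelection:
    """Which components were kept/removed and the correlations that decided.

    ``corr_matrix`` has one row per PPG component and one column per
    accelerometer axis (x, y, z).  When near-degenerate singular-value
    clusters were re-aligned against the accelerometer references before
    testing (see :func:`select_components`), ``removed_series`` carries the
    exact series that was subtracted from the window (for projection-mode
    removal this is the flagged components' reference-span projection).
    """

    kept: np.ndarray
    removed: np.ndarray
    corr_matrix: np.ndarray
    threshold: float
    removed_series: Optional[np.ndarray] = None


def _corr_against_axes(comps: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of comps (r, n) against refs (3, n)."""
    comps_c = comps - comps.mean(axis=1, keepdims=True)
    refs_c = refs - refs.mean(axis=1, keepdims=True)
    s_comp = np.linalg.norm(comps_c, axis=1)
    s_ref = np.linalg.norm(refs_c, axis=1)
    denom = s_comp[:, None] * s_ref[None, :]
    corr = np.zeros((comps.shape[0], refs.shape[0]))
    ok = denom > 0
    num = comps_c @ refs_c.T
    np.divide(num, denom, out=corr, where=ok)
    return np.clip(corr, -1.0, 1.0)


def select_components(ppg_hsvd: HankelSVD, accel: Sequence[Sequence[float]],
                      threshold: float = 0.5,
                      max_remove: Optional[int] = None,
                      correlation_mode: str = "accel_components",
                      energy_floor: Optional[float] = None,
                      removal: str = "projection",
                      ) -> ComponentSelection:
    """Flag PPG components correlated with the accelerometer for removal.

    A component is removed iff its maximum absolute Pearson correlation
    against the three reference series reaches ``threshold``, taking the
    most strongly correlated components first up to ``max_remove``
    (default: rank - 1).  At least one component is always kept.

    ``removal`` controls what is subtracted for each flagged component.
    ``"full"`` drops the whole component series.  ``"projection"``
    (default) drops only the component's least-squares projection onto the
    span of the reference series: for a genuine motion component the
    correlation is ~1 and this equals full removal, but when a finite
    window makes the SVD mix a heartbeat tone into a motion component (the
    two singular values being nearly equal), projection removal excises
    exactly the motion-correlated content and spares the heartbeat part.

    ``correlation_mode="accel_components"`` (default) correlates against
    the dominant component series of each axis' own Hankel embedding.
    Decomposing the accelerations as well separates each motion harmonic
    into its two spectral quadratures, so artifact components are caught
    regardless of phase and regardless of how the axis' energy is split
    across harmonics.  ``"raw_accel"`` correlates against the raw axes
    directly (simpler, but blind to the quadrature partner of each tone).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    if accel.shape[0] != 3 or accel.shape[1] != ppg_hsvd.n_samples:
        raise ValueError(
            f"accel must be 3 series of length {ppg_hsvd.n_samples}, "
            f"got shape {accel.shape}"
        )
    comps = all_component_series(ppg_hsvd)
    # reference series: raw axes, or the dominant component tones per axis
    ref_rows, ref_axis = [], []
    if correlation_mode == "raw_accel":
        for a, axis in enumerate(accel):
            ref_rows.append(axis)
            ref_axis.append(a)
    elif correlation_mode == "accel_components":
        for a, axis in enumerate(accel):
            refs = _dominant_component_series(axis)
            if refs is None:
                continue
            for row in refs:
                ref_rows.append(row)
                ref_axis.append(a)
    else:
        raise ValueError(f"unknown correlation_mode {correlation_mode!r}")

    if removal not in ("projection", "full"):
        raise ValueError(f"unknown removal mode {removal!r}")
    r = ppg_hsvd.rank
    refs = None
    if not ref_rows:
        corr = np.zeros((r, 3))
    else:
        refs = np.vstack(ref_rows)
        ref_axis = np.asarray(ref_axis)
        corr_full = _corr_against_axes(comps, refs)
        # collapse to one signed value per accelerometer axis
        corr = np.zeros((r, 3))
        for a in range(3):
            cols = np.flatnonzero(ref_axis == a)
            if cols.size:
                sub = corr_full[:, cols]
                best = np.argmax(np.abs(sub), axis=1)
                corr[:, a] = sub[np.arange(r), best]

    if max_remove is None:
        max_remove = r - 1
    max_corr = np.abs(corr).max(axis=1)
    candidates = np.flatnonzero(max_corr >= threshold)
    # strongest correlations removed first
    candidates = candidates[np.argsort(-max_corr[candidates])]
    removed = list(candidates[:max_remove])
    if energy_floor is not None and ppg_hsvd.S[0] > 0:
        weak = np.flatnonzero(ppg_hsvd.S < energy_floor * ppg_hsvd.S[0])
        removed.extend(i for i in weak if i not in set(removed))
    if len(removed) >= r:  # always keep at least one component
        removed = removed[: r - 1]
    removed_arr = np.asarray(sorted(removed), dtype=int)
    kept = np.setdiff1d(np.arange(r), removed_arr)
    if removed_arr.size == 0:
        removed_series = np.zeros(ppg_hsvd.n_samples)
    elif removal == "projection" and refs is not None:
        removed_series = _reference_projection(comps[removed_arr], refs)
    else:
        removed_series = comps[removed_arr].sum(axis=0)
    return ComponentSelection(kept=kept, removed=removed_arr,
                              corr_matrix=corr, threshold=threshold,
                              removed_series=removed_series)


def _reference_projection(flagged: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Least-squares projection of the flagged components' sum onto the
    (mean-removed) span of the reference series."""
    refs_c = refs - refs.mean(axis=1, keepdims=True)
    # orthonormal basis of the reference span
    q, rr = np.linalg.qr(refs_c.T)
    keep = np.abs(np.diag(rr)) > 1e-12 * max(1.0, np.abs(rr).max())
    q = q[:, keep]
    total = flagged.sum(axis=0)
    total_c = total - total.mean()
    return q @ (q.T @ total_c)


def _dominant_component_series(series: np.ndarray, energy: float = 0.999,
                               max_components: int = 8):
    """Top component series of one accel axis' Hankel embedding.

    Takes the smallest leading set capturing ``energy`` of the squared
    singular-value mass (capped at ``max_components``); returns None for a
    flat axis.
    """
    hsvd = decompose(series, channel_name="accel")
    total = float(np.sum(hsvd.S ** 2))
    if total == 0.0:
        return None
    cum = np.cumsum(hsvd.S ** 2) / total
    k = int(np.searchsorted(cum, energy) + 1)
    k = min(k, max_components, hsvd.rank)
    return np.vstack([component_series(hsvd, i) for i in range(k)])


def reconstruct(hsvd: HankelSVD, selection: ComponentSelection) -> np.ndarray:
    """Sum the kept component series (inverse of the decomposition).

    Computed as the original series minus the removed components, which is
    identical by linearity and cheaper when few components are removed.
    When the selection carries a ``removed_series`` (always set by
    :func:`select_components`), that series is subtracted directly.
    """
    kept = np.asarray(selection.kept, dtype=int)
    if kept.size == 0:
        raise ValueError("cannot reconstruct from an empty component set")
    removed = np.asarray(selection.removed, dtype=int)
    if removed.size == 0:
        return hsvd.series.copy()
    if selection.removed_series is not None and hsvd.series is not None:
        return hsvd.series - selection.removed_series
    if removed.size <= kept.size and hsvd.series is not None:
        drop = _subset_series(hsvd, removed)
        return hsvd.series - drop
    return _subset_series(hsvd, kept)


def _subset_series(hsvd: HankelSVD, idx: np.ndarray) -> np.ndarray:
    conv = scipy.signal.fftconvolve(hsvd.U[:, idx].T, hsvd.V[:, idx].T, axes=1)
    comp = hsvd.S[idx, None] * conv
    return comp.sum(axis=0) / _antidiag_counts(hsvd.L, hsvd.K)


def remove_motion_artifacts(ppg: Sequence[float],
                            accel: Sequence[Sequence[float]],
                            config: Optional[HankelMarConfig] = None,
                            ) -> Tuple[np.ndarray, ComponentSelection]:
    """One-call Hankel-MAR: decompose, select, reconstruct.

    Returns the cleaned PPG window and the component selection that
    produced it.
    """
    cfg = config if config is not None else HankelMarConfig()
    hsvd = decompose(ppg, channel_name="ppg")
    selection = select_components(
        hsvd, accel, threshold=cfg.threshold, max_remove=cfg.max_remove,
        correlation_mode=cfg.correlation_mode, energy_floor=cfg.energy_floor,
        removal=cfg.removal,
    )
    return reconstruct(hsvd, selection), selection
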