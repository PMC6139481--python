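"""Diffraction-anisotropy metrics.

The anisotropic temperature-factor tensor B (symmetric 3x3, angstrom^2)
describes direction-dependent attenuation of scattering.  With the
amplitude convention F(h) ~ exp(-B(n) s^2), s = sin(theta)/lambda = 1/(2d)
and n the unit diffraction direction, intensities fall off as
exp(-2 B(n) s^2).  The anisotropy magnitude ("delta-B") is the spread
b3 - b1 of the tensor eigenvalues, which is invariant under adding any
isotropic component.

The tensor is fitted by iterated linear least squares on log-intensity
residuals against per-shell means, with 3-sigma outlier rejection — a
deterministic stand-in for maximum-likelihood anisotropy refinement that
recovers the same eigenvalue spread on Wilson-distributed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import ReflectionSet

__all__ = [
    "AnisoTensor",
    "AnisoResult",
    "ShellBinning",
    "shell_binning",
    "wilson_b",
    "fit_aniso_tensor",
    "delta_b",
    "directional_limits",
    "delta_res",
    "aniso_ratio",
    "pct_rejected",
    "analyze_anisotropy",
]


class AnisoFitError(ValueError):
    """Not enough usable data, or degenerate reflection geometry."""


@dataclass(frozen=True)
class AnisoTensor:
    """Fitted anisotropic B tensor with its eigen-decomposition.

    ``eigenvalues`` are ascending (b1 <= b2 <= b3, angstrom^2);
    ``eigenvectors`` columns are the matching orthonormal principal axes
    of the anisotropy ellipsoid in the Cartesian frame.
    """

    b_cart: np.ndarray
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_cart, dtype=float)
        if b.shape != (3, 3) or not np.allclose(b, b.T, atol=1e-10):
            raise ValueError("B must be a symmetric 3x3 tensor")
        object.__setattr__(self, "b_cart", 0.5 * (b + b.T))
        w, v = np.linalg.eigh(self.b_cart)
        object.__setattr__(self, "eigenvalues", w)
        object.__setattr__(self, "eigenvectors", v)


@dataclass
class AnisoResult:
    """Per-entry anisotropy audit block.

    Amplitude- and intensity-based values are kept separately because
    deposited files carry either or both; absent paths stay ``None``.
    """

    aniso_b_amp: Optional[float] = None
    aniso_b_int: Optional[float] = None
    wilson_b_amp: Optional[float] = None
    wilson_b_int: Optional[float] = None
    ratio_amp: Optional[float] = None
    ratio_int: Optional[float] = None
    axis_limits: Optional[tuple[float, float, float]] = None
    limits_unreliable: Optional[tuple[bool, bool, bool]] = None
    delta_res: Optional[float] = None
    pct_rejected: Optional[float] = None
    n_reflections_total: int = 0
    n_rejected: int = 0


@dataclass
class ShellBinning:
    """Equal-count resolution shells, ordered from low to high resolution."""

    assignment: np.ndarray  # shell index per reflection, -1 = unusable
    mean_i: np.ndarray
    mean_d: np.ndarray
    mean_s2: np.ndarray  # shell mean of s^2, s = 1/(2d)
    counts: np.ndarray

    @property
    def n_shells(self) -> int:
        return len(self.mean_i)


def shell_binning(
    refl: ReflectionSet, n_shells: int = 20, source: str = "intensities"
) -> ShellBinning:
    """Partition reflections into near-equal-count resolution shells.

    Shells are ordered by decreasing d (shell 0 is lowest resolution);
    counts differ by at most one.  Reflections without a finite working
    intensity are assigned -1.
    """
    intens = refl.intensities(source)
    usable = np.isfinite(intens)
    n_use = int(usable.sum())
    if n_use < n_shells:
        raise AnisoFitError(
            f"{n_use} usable reflections for {n_shells} shells; reduce n_shells"
        )
    d = refl.d
    assignment = np.full(len(refl), -1, dtype=int)
    order = np.argsort(-d[usable], kind="stable")
    idx_usable = np.flatnonzero(usable)[order]
    bounds = np.linspace(0, n_use, n_shells + 1).round().astype(int)
    s2 = (0.5 / d) ** 2
    mean_i = np.empty(n_shells)
    mean_d = np.empty(n_shells)
    mean_s2 = np.empty(n_shells)
    counts = np.empty(n_shells, dtype=int)
    for j in range(n_shells):
        sel = idx_usable[bounds[j]:bounds[j + 1]]
        assignment[sel] = j
        mean_i[j] = intens[sel].mean()
        mean_d[j] = d[sel].mean()
        mean_s2[j] = s2[sel].mean()
        counts[j] = len(sel)
    return ShellBinning(assignment, mean_i, mean_d, mean_s2, counts)


def wilson_b(
    refl: ReflectionSet,
    source: str = "amplitudes",
    n_shells: int = 20,
    d_max_fit: float = 4.5,
) -> float:
    """Overall Wilson B-factor from the resolution falloff of <I>.

    Weighted least-squares line of ln<I> against the shell-mean s^2
    (s = 1/(2d)), over shells with mean d <= ``d_max_fit`` (the default
    4.5 A excludes the low-resolution regime where Wilson statistics do
    not hold).  The slope m gives B = -m/2.
    """
    shells = shell_binning(refl, n_shells=n_shells, source=source)
    in_range = shells.mean_d <= d_max_fit
    positive = shells.mean_i > 0
    if np.any(in_range & ~positive):
        warnings.warn("shells with non-positive mean intensity dropped from Wilson fit")
    use = in_range & positive
    if use.sum() < 3:
        raise AnisoFitError(
            f"only {int(use.sum())} shells inside the Wilson fit range (need >= 3)"
        )
    x = shells.mean_s2[use]
    y = np.log(shells.mean_i[use])
    w = shells.counts[use].astype(float)
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / np.sum(w * (x - xbar) ** 2)
    return float(-slope / 2.0)


def _design_matrix(q2_half: np.ndarray, n_hat: np.ndarray, shell_idx: np.ndarray, n_shells: int) -> np.ndarray:
    """Per-shell intercepts plus the six unique tensor components.

    Shell intercepts absorb the log of each shell's mean intensity
    exactly, so noise-free data fits with zero residual and no reflection
    is ever flagged as an outlier spuriously.
    """
    nx, ny, nz = n_hat[:, 0], n_hat[:, 1], n_hat[:, 2]
    dummies = np.zeros((len(q2_half), n_shells))
    dummies[np.arange(len(q2_half)), shell_idx] = 1.0
    return np.column_stack(
        [
            dummies,
            -q2_half * nx * nx,
            -q2_half * ny * ny,
            -q2_half * nz * nz,
            -2 * q2_half * nx * ny,
            -2 * q2_half * nx * nz,
            -2 * q2_half * ny * nz,
        ]
    )


def _tensor_from_params(p: np.ndarray) -> np.ndarray:
    bxx, byy, bzz, bxy, bxz, byz = p[-6:]
    return np.array([[bxx, bxy, bxz], [bxy, byy, byz], [bxz, byz, bzz]])


def fit_aniso_tensor(
    refl: ReflectionSet,
    source: str = "amplitudes",
    n_shells: int = 20,
    max_cycles: int = 5,
    reject_mult: float = 3.0,
) -> tuple[AnisoTensor, int]:
    """Fit the anisotropic B tensor to log-intensity residuals.

    The per-reflection residual y = ln(I / <I>_shell) is modelled as
    y = c_shell - (q^2/2) * (n' B n) with q = 1/d; the per-shell
    constants and the six unique tensor components are solved by linear
    least squares.
    Reflections with |y - yhat| > ``reject_mult`` * RMS are discarded and
    the fit repeated, up to ``max_cycles`` cycles or until the rejected
    set stabilizes.  The returned tensor is symmetrized over the
    point-group rotations of the space group; ``n_rejected`` counts the
    reflections excluded in the final cycle.

    Because shell means absorb the isotropic falloff, individual
    eigenvalues are determined only up to a common offset; their spread
    (delta-B) is the meaningful quantity.
    """
    intens = refl.intensities(source)
    usable = np.isfinite(intens) & (intens > 0)
    if usable.sum() < 50:
        raise AnisoFitError(f"{int(usable.sum())} usable reflections; need >= 50")
    n_hat_all = refl.unit_directions()
    if np.linalg.matrix_rank(n_hat_all[usable], tol=1e-8) < 3:
        raise AnisoFitError("reflection directions are coplanar; tensor is degenerate")

    shells = shell_binning(refl, n_shells=min(n_shells, int(usable.sum())), source=source)
    shell_ok = shells.mean_i > 0
    in_fit = usable & (shells.assignment >= 0) & shell_ok[np.clip(shells.assignment, 0, None)]
    y_all = np.full(len(refl), np.nan)
    y_all[in_fit] = np.log(intens[in_fit]) - np.log(shells.mean_i[shells.assignment[in_fit]])

    q2_half = 0.5 / refl.d**2  # (1/d)^2 / 2
    X_all = _design_matrix(
        q2_half, n_hat_all, np.clip(shells.assignment, 0, None), shells.n_shells
    )

    active = in_fit.copy()
    params = None
    n_rejected = 0
    for _ in range(max_cycles):
        X = X_all[active]
        y = y_all[active]
        used_cols = np.any(X != 0, axis=0)
        if np.linalg.matrix_rank(X[:, used_cols], tol=1e-10) < int(used_cols.sum()):
            raise AnisoFitError("rank-deficient design: reflections span too few directions")
        params, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid_all = y_all - X_all @ params
        rms = float(np.sqrt(np.mean(resid_all[active] ** 2)))
        if rms < 1e-8:  # exact fit (noise-free data): nothing is an outlier
            n_rejected = 0
            break
        keep = in_fit & (np.abs(resid_all) <= reject_mult * rms)
        n_rejected = int(in_fit.sum() - keep.sum())
        if np.array_equal(keep, active):
            break
        active = keep

    b = _tensor_from_params(params)
    rots = refl.spacegroup.cartesian_rotations(refl.cell)
    if len(rots) > 1:
        b = np.mean([r.T @ b @ r for r in rots], axis=0)
    return AnisoTensor(b_cart=0.5 * (b + b.T)), n_rejected


def delta_b(tensor: AnisoTensor) -> float:
    """Anisotropy magnitude: spread b3 - b1 of the tensor eigenvalues (A^2)."""
    return float(tensor.eigenvalues[-1] - tensor.eigenvalues[0])


@dataclass
class DirectionalLimits:
    limits: tuple[float, float, float]
    unreliable: tuple[bool, bool, bool]


def directional_limits(
    refl: ReflectionSet,
    axes: np.ndarray,
    threshold: float = 3.0,
    cone_deg: float = 20.0,
    n_bins: int = 10,
    min_cone_count: int = 20,
) -> DirectionalLimits:
    """Per-axis resolution limits where mean F/sigF drops below threshold.

    For each principal axis, reflections within ``cone_deg`` of the axis
    (Friedel pairs pooled, so +/-axis count together) are binned into
    ``n_bins`` equal-count resolution bins.  Walking from low to high
    resolution, the limit is the high-resolution edge (minimum d) of the
    last bin whose mean F/sigF still meets the threshold.  If the very
    first bin fails, the limit is the lowest-resolution d of the data;
    if no bin fails, it is the overall dmin of the data set — shared
    edges keep the three limits directly comparable.  Cones holding fewer
    than ``min_cone_count`` usable reflections are flagged unreliable.
    """
    f, sig_f = refl.amplitudes_for_limits()
    ok = np.isfinite(f) & np.isfinite(sig_f) & (sig_f > 0)
    if not np.any(ok):
        raise AnisoFitError("no reflections with usable F and sigma(F)")
    fsig = np.full(len(refl), np.nan)
    fsig[ok] = f[ok] / sig_f[ok]
    d = refl.d
    d_lo = float(d[ok].max())  # lowest resolution present
    d_hi = float(d[ok].min())  # overall dmin
    n_hat = refl.unit_directions()
    cos_cut = np.cos(np.radians(cone_deg))

    axes = np.asarray(axes, dtype=float)
    if axes.shape == (3, 3):
        axis_list = [axes[:, j] for j in range(3)]
    else:
        axis_list = [np.asarray(a, dtype=float) for a in axes]

    limits: list[float] = []
    flags: list[bool] = []
    for axis in axis_list:
        axis = axis / np.linalg.norm(axis)
        in_cone = ok & (np.abs(n_hat @ axis) >= cos_cut)
        n_sel = int(in_cone.sum())
        flags.append(n_sel < min_cone_count)
        if n_sel == 0:
            limits.append(d_lo)
            continue
        sel = np.flatnonzero(in_cone)
        order = sel[np.argsort(-d[sel], kind="stable")]
        nb = min(n_bins, len(order))
        bounds = np.linspace(0, len(order), nb + 1).round().astype(int)
        limit = None
        for j in range(nb):
            bin_idx = order[bounds[j]:bounds[j + 1]]
            if fsig[bin_idx].mean() >= threshold:
                limit = float(d[bin_idx].min())
            else:
                break
        if limit is None:  # first bin already fails
            limit = d_lo
        elif j == nb - 1 and fsig[order[bounds[nb - 1]:bounds[nb]]].mean() >= threshold:
            limit = d_hi  # no bin failed: data edge
        limits.append(limit)
    return DirectionalLimits(limits=tuple(limits), unreliable=tuple(flags))


def delta_res(limits) -> float:
    """Spread of the three directional resolution limits (A, >= 0)."""
    arr = np.asarray(limits, dtype=float)
    if arr.shape != (3,) or np.any(arr <= 0):
        raise ValueError("delta_res needs 3 positive resolution limits")
    return float(arr.max() - arr.min())


def aniso_ratio(aniso_b_value: float, wilson_b_value: Optional[float]) -> Optional[float]:
    """delta-B over Wilson B; None (flagged absent) when Wilson B <= 0."""
    if wilson_b_value is None or wilson_b_value <= 0:
        return None
    return float(aniso_b_value / wilson_b_value)


def pct_rejected(n_rejected: int, n_total: int) -> float:
    """Percentage of reflections rejected during the anisotropy fit."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_rejected <= n_total:
        raise ValueError("n_rejected must be between 0 and n_total")
    return 100.0 * n_rejected / n_total


def analyze_anisotropy(
    refl: ReflectionSet,
    n_shells: int = 20,
    threshold: float = 3.0,
    cone_deg: float = 20.0,
    n_bins: int = 10,
) -> AnisoResult:
    """Run the full anisotropy audit on one reflection set.

    Amplitude- and intensity-based delta-B, Wilson B and their ratio are
    computed for whichever data paths the file provides.  Directional
    limits use the principal axes of the amplitude-path tensor when
    available, else the intensity-path tensor.
    """
    res = AnisoResult(n_reflections_total=len(refl))
    tensors: dict[str, AnisoTensor] = {}
    for source, b_attr, w_attr, r_attr in [
        ("amplitudes", "aniso_b_amp", "wilson_b_amp", "ratio_amp"),
        ("intensities", "aniso_b_int", "wilson_b_int", "ratio_int"),
    ]:
        if not refl.has_source(source):
            continue
        try:
            tensor, n_rej = fit_aniso_tensor(refl, source=source, n_shells=n_shells)
        except AnisoFitError:
            continue
        tensors[source] = tensor
        setattr(res, b_attr, delta_b(tensor))
        if source == "amplitudes" or "amplitudes" not in tensors:
            res.n_rejected = n_rej
        try:
            setattr(res, w_attr, wilson_b(refl, source=source, n_shells=n_shells))
        except AnisoFitError:
            pass
        setattr(res, r_attr, aniso_ratio(getattr(res, b_attr), getattr(res, w_attr)))
    if tensors:
        axes_tensor = tensors.get("amplitudes", next(iter(tensors.values())))
        try:
            dl = directional_limits(
                refl, axes_tensor.eigenvectors, threshold=threshold,
                cone_deg=cone_deg, n_bins=n_bins,
            )
            res.axis_limits = dl.limits
            res.limits_unreliable = dl.unreliable
            res.delta_res = delta_res(dl.limits)
        except AnisoFitError:
            pass
        res.pct_rejected = pct_rejected(res.n_rejected, len(refl))
    return res
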