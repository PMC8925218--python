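"""Strain/stress mechanics and the nonlinear Kelvin-Voigt fit.

The heel pad is modelled as a spring and dashpot in parallel with the
viscous term scaled by strain (Gefen's nonlinear Kelvin-Voigt form):

    sigma = E * eps + eta * eps * deps/dt

with compressive strain and stress taken positive. ``eps`` is the change in
pad thickness divided by the primary (first-contact) thickness, ``sigma``
the heel-ground force over the heel contact area (kPa), and ``deps/dt`` the
tangent of the strain-time curve. E (kPa) and eta (kPa*s) are estimated by
unweighted linear least squares on the regressors [eps, eps*deps/dt]; the
model has no intercept and the fit is unconstrained — negative estimates
are flagged, never clipped, since clipping would bias cohort medians.

Energy dissipation is the area enclosed by the stress-strain hysteresis
loop over one loading/unloading cycle; the energy dissipation rate (EDR)
is that area as a percentage of the area under the loading branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.signal import savgol_filter

from . import geometry
from .errors import (
    DegenerateCurveError,
    DegenerateLoopWarning,
    EmptyInputError,
    InvalidStateError,
    StageError,
    UnidentifiableModelError,
    UnitError,
)

__all__ = [
    "TrialTimeSeries",
    "ViscoFit",
    "HeelProperties",
    "compute_strain",
    "compute_stress",
    "strain_rate",
    "fit_kelvin_voigt",
    "split_loading_unloading",
    "energy_dissipation_rate",
    "peak_values",
    "analyze_trial",
]

#: kPa per (N / cm^2)
KPA_PER_N_CM2 = 10.0


@dataclass
class TrialTimeSeries:
    """One stance-phase recording for one heel.

    Raw channels: ``time`` (s, strictly increasing, nominally 1/50 s apart),
    ``thickness`` (mm), ``force`` (N), ``area`` (cm^2, scalar broadcast or
    per-frame). Derived channels (``strain``, ``stress``, ``strain_rate_``)
    are populated by the operations below. ``contact_index`` is the frame of
    initial heel-plate contact when known (the simulator records it; for
    force-only recordings it is detected from a force threshold). ``h0`` is
    the primary thickness once established.
    """

    time: NDArray[np.float64]
    thickness: NDArray[np.float64]
    force: NDArray[np.float64]
    area: NDArray[np.float64]
    contact_index: int | None = None
    h0: float | None = None
    strain: NDArray[np.float64] | None = None
    stress: NDArray[np.float64] | None = None
    strain_rate_: NDArray[np.float64] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.area = np.broadcast_to(
            np.asarray(self.area, dtype=float), self.time.shape
        ).copy()
        n = self.time.size
        if not (self.thickness.size == self.force.size == n):
            raise ValueError("time, thickness, force must have equal length")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time.size)

    def cropped(self, start: int) -> "TrialTimeSeries":
        """Copy restricted to frames from `start` on (stance proper)."""
        return TrialTimeSeries(
            time=self.time[start:],
            thickness=self.thickness[start:],
            force=self.force[start:],
            area=self.area[start:],
            contact_index=0,
            h0=self.h0,
            meta=dict(self.meta),
        )


@dataclass
class ViscoFit:
    """Least-squares Kelvin-Voigt estimates with residual diagnostics."""

    E: float  # kPa
    eta: float  # kPa*s
    rss: float  # kPa^2
    r_squared: float
    n_frames: int
    negative_param_flag: bool


@dataclass
class HeelProperties:
    """The six per-heel endpoints of the pipeline."""

    primary_thickness: float  # mm
    peak_strain: float
    peak_stress: float  # kPa
    E: float  # kPa
    eta: float  # kPa*s
    edr: float  # %
    fit: ViscoFit | None = None
    flags: list[str] = field(default_factory=list)

    _FIELDS = ("primary_thickness", "peak_strain", "peak_stress", "E", "eta", "edr")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._FIELDS}


def compute_strain(ts: TrialTimeSeries) -> NDArray[np.float64]:
    """Compressive strain (h0 - thickness) / h0; zero at the contact frame."""
    if ts.h0 is None or ts.h0 <= 0:
        raise InvalidStateError("primary thickness h0 must be set and positive")
    ts.strain = (ts.h0 - ts.thickness) / ts.h0
    return ts.strain


def compute_stress(ts: TrialTimeSeries) -> NDArray[np.float64]:
    """Compressive stress force/area, converted N/cm^2 -> kPa (factor 10)."""
    in_contact = ts.force > 0
    bad = in_contact & (ts.area <= 0)
    if bad.any():
        raise UnitError(
            f"non-positive heel area on in-contact frame {int(np.argmax(bad))}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = KPA_PER_N_CM2 * ts.force / ts.area
    sigma = np.where(ts.force == 0, 0.0, sigma)
    ts.stress = sigma
    return sigma


def strain_rate(
    strain: ArrayLike,
    time: ArrayLike,
    smoothing: bool = False,
    window: int = 5,
    polyorder: int = 2,
) -> NDArray[np.float64]:
    """Tangent of the strain-time curve, 1/s.

    Central finite differences on interior frames, one-sided at the
    endpoints (exact for quadratics in the uniform-grid interior). With
    ``smoothing`` a local-polynomial (Savitzky-Golay) filter of the given
    window and degree is applied to the strain first — useful on noisy
    recordings, off by default so noise-free data differentiates exactly.
    """
    eps = np.asarray(strain, dtype=float)
    t = np.asarray(time, dtype=float)
    if eps.size < 3:
        raise ValueError("need at least 3 frames to differentiate")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time must be strictly increasing")
    if smoothing:
        w = min(window, eps.size if eps.size % 2 == 1 else eps.size - 1)
        eps = savgol_filter(eps, window_length=w, polyorder=min(polyorder, w - 1))
    return np.gradient(eps, t)


def fit_kelvin_voigt(
    stress: ArrayLike, strain: ArrayLike, strain_rate: ArrayLike
) -> ViscoFit:
    """Estimate (E, eta) minimising sum (sigma - E*eps - eta*eps*epsdot)^2.

    Solved by orthogonal factorisation (lstsq) on the two-column regressor
    matrix [eps, eps*epsdot]; no intercept. Unconstrained: negative
    estimates set ``negative_param_flag``.

    Raises
    ------
    UnidentifiableModelError
        If the regressor matrix has rank < 2 (message names the degenerate
        column, e.g. the viscous column when eps*epsdot is identically 0).
    """
    sigma = np.asarray(stress, dtype=float)
    eps = np.asarray(strain, dtype=float)
    epsdot = np.asarray(strain_rate, dtype=float)
    if not (sigma.size == eps.size == epsdot.size):
        raise ValueError("stress, strain, strain_rate must have equal length")
    if sigma.size < 3:
        raise ValueError("need at least 3 frames to fit")
    X = np.column_stack([eps, eps * epsdot])
    norms = np.linalg.norm(X, axis=0)
    if norms[0] == 0.0:
        raise UnidentifiableModelError("elastic column eps is identically zero")
    if norms[1] == 0.0:
        raise UnidentifiableModelError(
            "viscous column eps*epsdot is identically zero; eta unidentifiable"
        )
    if np.linalg.matrix_rank(X) < 2:
        raise UnidentifiableModelError(
            "regressor columns eps and eps*epsdot are proportional"
        )
    coef, _, _, _ = np.linalg.lstsq(X, sigma, rcond=None)
    resid = sigma - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((sigma - sigma.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
    E, eta = float(coef[0]), float(coef[1])
    return ViscoFit(
        E=E,
        eta=eta,
        rss=rss,
        r_squared=r2,
        n_frames=int(sigma.size),
        negative_param_flag=bool(E < 0 or eta < 0),
    )


def split_loading_unloading(
    strain: ArrayLike,
) -> tuple[NDArray[np.intp], NDArray[np.intp]]:
    """Split a strain cycle at its first global maximum.

    The maximal frame belongs to both branches so the hysteresis loop is
    contiguous. A monotone series triggers :class:`DegenerateLoopWarning`
    and an unloading branch of length 1.
    """
    eps = np.asarray(strain, dtype=float)
    if eps.size == 0:
        raise EmptyInputError("empty strain series")
    imax = int(np.argmax(eps))
    loading = np.arange(0, imax + 1)
    unloading = np.arange(imax, eps.size)
    if unloading.size == 1:
        warnings.warn(
            "monotone strain: unloading branch has a single frame",
            DegenerateLoopWarning,
            stacklevel=2,
        )
    return loading, unloading


def _shoelace(x: NDArray[np.float64], y: NDArray[np.float64]) -> float:
    """Signed polygon area by the shoelace formula (implicitly closed)."""
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def energy_dissipation_rate(
    stress: ArrayLike, strain: ArrayLike
) -> tuple[float, float]:
    """Hysteresis-loop energy dissipation (kPa) and EDR (%).

    The loop polygon follows the loading branch up and the unloading branch
    back; if the cycle does not end where it began, the polygon is closed by
    the chord from the last to the first point. Loop area is the absolute
    shoelace area; the loading area is the trapezoid integral of sigma
    d(eps) over the loading branch; EDR = 100 * |loop| / loading.

    Raises
    ------
    DegenerateCurveError
        If the loading branch has non-positive area under it.
    """
    sigma = np.asarray(stress, dtype=float)
    eps = np.asarray(strain, dtype=float)
    loading, unloading = split_loading_unloading(eps)
    loading_area = float(np.trapezoid(sigma[loading], eps[loading]))
    if loading_area <= 0:
        raise DegenerateCurveError(
            f"area under loading branch is {loading_area:.3g} kPa (must be > 0)"
        )
    # polygon: loading up, unloading back, shoelace closes last->first
    order = np.concatenate([loading, unloading[1:]])
    dissipation = abs(_shoelace(eps[order], sigma[order]))
    return dissipation, 100.0 * dissipation / loading_area


def peak_values(
    stress: ArrayLike, strain: ArrayLike
) -> tuple[float, float, int, int]:
    """Independent channel maxima: (peak_strain, peak_stress, i_strain, i_stress).

    The two maxima are located independently — their frames need not
    coincide, since the viscous contribution peaks before maximal strain.
    """
    sigma = np.asarray(stress, dtype=float)
    eps = np.asarray(strain, dtype=float)
    if sigma.size == 0 or eps.size == 0:
        raise EmptyInputError("empty stress or strain series")
    i_eps = int(np.argmax(eps))
    i_sig = int(np.argmax(sigma))
    return float(eps[i_eps]), float(sigma[i_sig]), i_eps, i_sig


def analyze_trial(
    ts: TrialTimeSeries,
    plane: "geometry.Plane | None" = None,
    scene: "geometry.GeometryScene | None" = None,
    contact_threshold_n: float = 10.0,
    min_consecutive: int = 1,
    smoothing: bool = False,
) -> HeelProperties:
    """Run the full per-heel pipeline and return :class:`HeelProperties`.

    Stages: contact detection -> primary thickness -> strain / stress /
    strain-rate -> peaks -> Kelvin-Voigt fit -> hysteresis EDR. When a
    ``scene`` is given, the thickness channel is recomputed from geometry
    (plane from the scene's ball markers unless ``plane`` is supplied);
    otherwise the trial's thickness channel is used directly. The annotated
    ``ts.contact_index`` (the simulator's touch-down frame, standing in for
    the radiographic identification) takes precedence; without it, contact
    is detected as the first frame where force holds >= the threshold.

    Errors from any stage are re-raised as :class:`StageError` tagged with
    the stage name.
    """

    def run(stage: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - tagged and re-raised
            raise StageError(stage, exc) from exc

    if scene is not None:
        thickness = run("geometry", geometry.scene_thickness_channel, scene, plane)
        ts = TrialTimeSeries(
            time=ts.time,
            thickness=thickness,
            force=ts.force,
            area=ts.area,
            contact_index=ts.contact_index,
            meta=dict(ts.meta),
        )

    if ts.contact_index is not None:
        contact = int(ts.contact_index)
    else:
        contact = run(
            "contact",
            geometry.detect_contact_frame,
            ts.force,
            contact_threshold_n,
            min_consecutive,
        )

    h0 = run("primary_thickness", geometry.primary_thickness, ts.thickness, contact)
    stance = ts.cropped(contact)
    if len(stance) < 3:
        raise StageError("crop", ValueError("fewer than 3 frames after contact"))
    stance.h0 = h0

    eps = run("strain", compute_strain, stance)
    sigma = run("stress", compute_stress, stance)
    epsdot = run("strain_rate", strain_rate, eps, stance.time, smoothing)
    peak_eps, peak_sigma, _, _ = run("peaks", peak_values, sigma, eps)
    fit = run("fit", fit_kelvin_voigt, sigma, eps, epsdot)
    _, edr = run("edr", energy_dissipation_rate, sigma, eps)

    flags = []
    if fit.negative_param_flag:
        flags.append("negative_modulus")
    if not 0.0 <= edr <= 100.0:
        flags.append("edr_out_of_range")
    if not 0.0 <= peak_eps < 1.0:
        flags.append("peak_strain_out_of_range")
    return HeelProperties(
        primary_thickness=h0,
        peak_strain=peak_eps,
        peak_stress=peak_sigma,
        E=fit.E,
        eta=fit.eta,
        edr=edr,
        fit=fit,
        flags=flags,
    )
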