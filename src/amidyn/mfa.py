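"""Model-free analysis of two-field backbone :sup:`15`\\ N relaxation.

Implements the Lipari-Szabo treatment of amide N-H bond dynamics on top of
a fully anisotropic (asymmetric-rotor) rotational diffusion tensor.  For a
C2-symmetric homodimer whose symmetry axis is aligned with the molecular z
axis, the tensor orientation reduces to a single Euler angle ``gamma``
about z (``alpha = beta = 0``), leaving four global parameters
``(D1, D2, D3, gamma)``.  Per residue, fast local motion is described by an
order parameter ``S2`` and internal correlation time ``tau_int``; slow
us-ms exchange enters as an ``Rex`` addition to R2 that scales with the
square of the static field.

The spectral density is the Woessner asymmetric-rotor result

.. math::

    J(\\omega) = \\tfrac{2}{5} \\sum_{k=1}^{5} A_k \\left[
        \\frac{S^2 \\tau_k}{1 + (\\omega\\tau_k)^2}
      + \\frac{(1 - S^2)\\tau_k'}{1 + (\\omega\\tau_k')^2} \\right],
    \\qquad \\frac{1}{\\tau_k'} = \\frac{1}{\\tau_k} + \\frac{1}{\\tau_{int}}

with the five correlation times and amplitudes determined by the tensor
eigenvalues and the direction cosines of the N-H vector in the tensor
frame.

The same forward model doubles as the simulator behind
:mod:`amidyn.synth`, which is what makes round-trip (generate -> fit)
validation possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from sklearn.base import BaseEstimator

from .constants import DEFAULT_CONSTANTS, NMRConstants

logger = logging.getLogger(__name__)

OBSERVABLES = ("R1", "R2", "NOE")

#: model_id -> free local parameters (S2 always present)
LOCAL_MODELS: dict[str, tuple[str, ...]] = {
    "M0": ("S2",),
    "M1": ("S2", "tau_int"),
    "M2": ("S2", "Rex"),
    "M3": ("S2", "tau_int", "Rex"),
}

_TAU_INT_MAX = 5e-9  # s; internal motions slower than this are outside scope
_REX_MAX = 60.0  # s^-1 at the reference field


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiffusionTensor:
    """Principal rotational diffusion rates and in-plane orientation.

    ``gamma_deg`` rotates the tensor frame about the molecular z axis
    (the C2 symmetry axis); ``alpha = beta = 0`` by construction.
    """

    D1: float
    D2: float
    D3: float
    gamma_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.D1, self.D2, self.D3) <= 0:
            raise ValueError("principal diffusion rates must be positive")

    @property
    def D_iso(self) -> float:
        return (self.D1 + self.D2 + self.D3) / 3.0

    @property
    def tau_c(self) -> float:
        """Effective overall correlation time 1/(6 D_iso), seconds."""
        return 1.0 / (6.0 * self.D_iso)

    @property
    def anisotropy(self) -> float:
        """Ratio of the largest to smallest principal rate."""
        return max(self.D1, self.D2, self.D3) / min(self.D1, self.D2, self.D3)

    def canonical(self) -> "DiffusionTensor":
        """Resolve the (D1,D2,gamma) <-> (D2,D1,gamma+90) degeneracy.

        Swapping the two in-plane principal rates while rotating gamma by
        90 degrees leaves J(omega) invariant, as does gamma -> gamma+180.
        The canonical representative has D1 <= D2 and gamma in [0, 180).
        """
        D1, D2, g = self.D1, self.D2, self.gamma_deg
        if D1 > D2:
            D1, D2, g = D2, D1, g + 90.0
        return replace(self, D1=D1, D2=D2, gamma_deg=g % 180.0)


@dataclass
class LocalDynamics:
    """Per-residue model-free parameters (errors filled in by MC)."""

    residue_id: str
    S2: float
    tau_int: float = 0.0
    Rex: float = 0.0
    model_id: str = "M3"
    S2_err: float = np.nan
    tau_int_err: float = np.nan
    Rex_err: float = np.nan
    chi2: float = np.nan
    flags: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.S2 <= 1.0):
            raise ValueError(f"S2 = {self.S2} outside [0, 1]")
        if self.tau_int < 0 or self.Rex < 0:
            raise ValueError("tau_int and Rex must be non-negative")


@dataclass
class DynamicsModel:
    """Result bundle of a model-free run."""

    tensor: DiffusionTensor
    locals: dict[str, LocalDynamics]
    chi2_global: float
    ref_field_MHz: float
    fields_MHz: tuple[float, float]
    excluded: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue_id": ld.residue_id,
                "S2": ld.S2,
                "S2_err": ld.S2_err,
                "tau_int": ld.tau_int,
                "tau_int_err": ld.tau_int_err,
                "Rex": ld.Rex,
                "Rex_err": ld.Rex_err,
                "model_id": ld.model_id,
                "chi2": ld.chi2,
                "flags": ld.flags,
            }
            for ld in self.locals.values()
        ]
        return pd.DataFrame(rows).set_index("residue_id").sort_index()


# ---------------------------------------------------------------------------
# spectral density
# ---------------------------------------------------------------------------


def woessner_components(
    tensor: DiffusionTensor, vectors: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation times and amplitudes of the asymmetric-rotor J(omega).

    Parameters
    ----------
    tensor : DiffusionTensor
    vectors : ndarray, shape (n, 3)
        Unit N-H vectors in the molecular frame (z = C2 axis).

    Returns
    -------
    A : ndarray, shape (n, 5)
        Amplitudes, summing to 1 per vector.
    tau : ndarray, shape (5,)
        Correlation times in seconds.
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(v, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("N-H vectors must be unit-norm")
    g = np.deg2rad(tensor.gamma_deg)
    # components of v in the tensor principal frame (rotation by -gamma about z)
    x = np.cos(g) * v[:, 0] + np.sin(g) * v[:, 1]
    y = -np.sin(g) * v[:, 0] + np.cos(g) * v[:, 1]
    z = v[:, 2]

    D1, D2, D3 = tensor.D1, tensor.D2, tensor.D3
    Diso = tensor.D_iso
    L2 = (D1 * D2 + D1 * D3 + D2 * D3) / 3.0
    delta_sq = max(Diso * Diso - L2, 0.0)
    Delta = np.sqrt(delta_sq)

    tau = 1.0 / np.array(
        [
            4 * D1 + D2 + D3,
            D1 + 4 * D2 + D3,
            D1 + D2 + 4 * D3,
            6 * (Diso + Delta),
            6 * max(Diso - Delta, 1e-300),
        ]
    )

    x2, y2, z2 = x * x, y * y, z * z
    x4, y4, z4 = x2 * x2, y2 * y2, z2 * z2
    d = 0.25 * (3.0 * (x4 + y4 + z4) - 1.0)
    if Delta / Diso < 1e-9:
        # isotropic limit: delta_i -> 0/0; the e-term vanishes by symmetry
        e = np.zeros_like(d)
    else:
        d1, d2, d3 = (D1 - Diso) / Delta, (D2 - Diso) / Delta, (D3 - Diso) / Delta
        e = (
            d1 * (3 * x4 + 6 * y2 * z2 - 1)
            + d2 * (3 * y4 + 6 * x2 * z2 - 1)
            + d3 * (3 * z4 + 6 * x2 * y2 - 1)
        ) / 12.0
    A = np.stack(
        [3 * y2 * z2, 3 * x2 * z2, 3 * x2 * y2, d - e, d + e], axis=-1
    )
    return A, tau


def _J(
    A: np.ndarray,
    tau: np.ndarray,
    S2: np.ndarray,
    tau_int: np.ndarray,
    omegas: np.ndarray,
) -> np.ndarray:
    """Vectorised J(omega); see module docstring for the formula.

    Shapes: A (n,5), tau (5,), S2/tau_int broadcastable to (..., n),
    omegas (m,).  Returns (..., n, m).
    """
    S2 = np.asarray(S2, dtype=float)[..., None, None]  # (...,n,1,1)
    ti = np.asarray(tau_int, dtype=float)[..., None, None]
    tau_c = tau[:, None]  # (5,1)
    om = np.asarray(omegas, dtype=float)[None, :]  # (1,m)
    slow = tau_c / (1.0 + (om * tau_c) ** 2)  # (5,m)
    with np.errstate(divide="ignore", invalid="ignore"):
        tp = np.where(ti > 0, tau_c * ti / (tau_c + ti), 0.0)  # (...,n?,5,1)
    fast = tp / (1.0 + (om * tp) ** 2)
    terms = S2 * slow + (1.0 - S2) * fast  # (...,n,5,m)
    return 0.4 * np.sum(A[..., :, :, None] * terms, axis=-2)


def anisotropic_J(
    omega: float | np.ndarray,
    tensor: DiffusionTensor,
    nh_vector: np.ndarray,
    S2: float = 1.0,
    tau_int: float = 0.0,
) -> float | np.ndarray:
    """Spectral density J(omega) for one N-H vector (s/rad).

    ``omega`` may be a scalar or an array of angular frequencies.
    """
    if not (0.0 <= S2 <= 1.0):
        raise ValueError("S2 must lie in [0, 1]")
    if tau_int < 0:
        raise ValueError("tau_int must be non-negative")
    A, tau = woessner_components(tensor, np.atleast_2d(nh_vector))
    om = np.atleast_1d(np.asarray(omega, dtype=float))
    out = _J(A, tau, np.array([S2]), np.array([tau_int]), om)[0]
    return float(out[0]) if np.isscalar(omega) else out


def predict_rates(
    tensor: DiffusionTensor,
    vectors: np.ndarray,
    S2,
    tau_int,
    Rex,
    fields_MHz: Sequence[float],
    constants: NMRConstants = DEFAULT_CONSTANTS,
    ref_field_MHz: float = 700.0,
) -> np.ndarray:
    """Forward relaxation model, vectorised over residues and grids.

    Parameters broadcast: ``S2``, ``tau_int``, ``Rex`` may have any shape
    ending in (or broadcastable to) the number of residues ``n`` given by
    ``vectors``.  Returns an array of shape ``(..., n, n_fields, 3)`` with
    the last axis ordered (R1, R2, NOE).
    """
    vectors = np.atleast_2d(vectors)
    A, tau = woessner_components(tensor, vectors)
    S2, tau_int, Rex = np.broadcast_arrays(
        np.asarray(S2, float), np.asarray(tau_int, float), np.asarray(Rex, float)
    )
    d2 = constants.d2
    gr = constants.gamma_H / constants.gamma_N
    out = []
    for f in fields_MHz:
        wH, wN = constants.omega_H(f), constants.omega_N(f)
        om = np.array([0.0, wN, wH - wN, wH, wH + wN])
        J = _J(A, tau, S2, tau_int, om)  # (...,n,5)
        J0, JN, JmHN, JH, JpHN = (J[..., i] for i in range(5))
        c2 = constants.c2(f)
        R1 = (d2 / 4.0) * (JmHN + 3 * JN + 6 * JpHN) + c2 * JN
        R2 = (
            (d2 / 8.0) * (4 * J0 + JmHN + 3 * JN + 6 * JH + 6 * JpHN)
            + (c2 / 6.0) * (4 * J0 + 3 * JN)
            + Rex * (f / ref_field_MHz) ** 2
        )
        NOE = 1.0 + gr * (d2 / 4.0) * (6 * JpHN - JmHN) / R1
        out.append(np.stack([R1, R2, NOE], axis=-1))
    return np.stack(out, axis=-2)


def predict_observables(
    tensor: DiffusionTensor,
    nh_vector: np.ndarray,
    local: LocalDynamics,
    field_MHz: float,
    constants: NMRConstants = DEFAULT_CONSTANTS,
    ref_field_MHz: float = 700.0,
) -> tuple[float, float, float]:
    """(R1, R2, NOE) for a single residue at one field."""
    obs = predict_rates(
        tensor,
        np.atleast_2d(nh_vector),
        np.array([local.S2]),
        np.array([local.tau_int]),
        np.array([local.Rex]),
        [field_MHz],
        constants,
        ref_field_MHz,
    )
    return tuple(float(v) for v in obs[0, 0])


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------


def _records_to_arrays(
    records: pd.DataFrame, fields_MHz: Sequence[float]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pivot a long-format record table into (residues, obs, err) arrays.

    Returns obs/err of shape (n, n_fields, 3); only residues complete at
    every field are kept (the caller is expected to have run
    :func:`amidyn.rates.assemble_records` already, this is a safety net).
    """
    need = {"residue_id", "field_MHz", *OBSERVABLES}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns: {sorted(missing)}")
    ids, obs, err = [], [], []
    for rid, grp in records.groupby("residue_id", sort=True):
        rows = []
        for f in fields_MHz:
            sel = grp[np.isclose(grp["field_MHz"], f)]
            if len(sel) != 1:
                rows = None
                break
            rows.append(sel.iloc[0])
        if rows is None:
            continue
        ids.append(str(rid))
        obs.append([[r[o] for o in OBSERVABLES] for r in rows])
        err.append(
            [[r.get(f"{o}_err", 0.0) for o in OBSERVABLES] for r in rows]
        )
    return ids, np.asarray(obs, float), np.asarray(err, float)


def _effective_err(obs: np.ndarray, err: np.ndarray) -> np.ndarray:
    """Fit weights: stated errors with a 0.1% floor so exact synthetic
    data (zero stated error) still yields a defined weighted problem."""
    floor = 1e-3 * np.maximum(np.abs(obs), 1e-12)
    return np.maximum(err, floor)


# ---------------------------------------------------------------------------
# local fits and model selection
# ---------------------------------------------------------------------------


def _local_residuals(params, model_id, A, tau, obs, err, fields, constants, ref_field):
    # params are scaled: tau_int carried in ns so all parameters are O(1)
    names = LOCAL_MODELS[model_id]
    p = dict(zip(names, params))
    S2 = p["S2"]
    ti = p.get("tau_int", 0.0) * 1e-9
    rex = p.get("Rex", 0.0)
    pred = _rates_from_components(
        A, tau, np.array([S2]), np.array([ti]), np.array([rex]),
        fields, constants, ref_field,
    )[0]
    return ((pred - obs) / err).ravel()


def _rates_from_components(A, tau, S2, tau_int, Rex, fields, constants, ref_field):
    """Same as predict_rates but reusing precomputed Woessner components."""
    d2 = constants.d2
    gr = constants.gamma_H / constants.gamma_N
    out = []
    for f in fields:
        wH, wN = constants.omega_H(f), constants.omega_N(f)
        om = np.array([0.0, wN, wH - wN, wH, wH + wN])
        J = _J(A, tau, S2, tau_int, om)
        J0, JN, JmHN, JH, JpHN = (J[..., i] for i in range(5))
        c2 = constants.c2(f)
        R1 = (d2 / 4.0) * (JmHN + 3 * JN + 6 * JpHN) + c2 * JN
        R2 = (
            (d2 / 8.0) * (4 * J0 + JmHN + 3 * JN + 6 * JH + 6 * JpHN)
            + (c2 / 6.0) * (4 * J0 + 3 * JN)
            + np.asarray(Rex) * (f / ref_field) ** 2
        )
        NOE = 1.0 + gr * (d2 / 4.0) * (6 * JpHN - JmHN) / R1
        out.append(np.stack([R1, R2, NOE], axis=-1))
    return np.stack(out, axis=-2)


def aicc(chi2: float, n_params: int, n_obs: int = 6) -> float:
    """Small-sample corrected information criterion for weighted chi^2."""
    k = n_params
    return chi2 + 2.0 * k + 2.0 * k * (k + 1.0) / (n_obs - k - 1.0)


def select_model(candidates: Mapping[str, tuple[np.ndarray, float]]) -> str:
    """Pick the candidate with minimal AICc; ties go to fewer parameters.

    ``candidates`` maps model_id -> (params, chi2) for converged fits.
    """
    if not candidates:
        raise ValueError("no converged candidate models")
    scored = sorted(
        (
            (aicc(chi2, len(LOCAL_MODELS[mid])), len(LOCAL_MODELS[mid]), mid)
            for mid, (_, chi2) in candidates.items()
        ),
    )
    best_score = scored[0][0]
    # tie-break explicitly toward fewer parameters at (near-)equal AICc
    tied = [s for s in scored if s[0] <= best_score + 1e-9]
    return min(tied, key=lambda s: (s[1], s[2]))[2]


def fit_local(
    obs: np.ndarray,
    err: np.ndarray,
    tensor: DiffusionTensor,
    nh_vector: np.ndarray,
    fields_MHz: Sequence[float],
    constants: NMRConstants = DEFAULT_CONSTANTS,
    ref_field_MHz: float = 700.0,
    residue_id: str = "",
    force_model: str | None = None,
) -> LocalDynamics:
    """Fit the nested local models to one residue's two-field observables.

    ``obs``/``err`` have shape (n_fields, 3) ordered (R1, R2, NOE).
    Model selection by AICc unless ``force_model`` names one model.
    """
    obs = np.asarray(obs, float)
    err = _effective_err(obs, np.asarray(err, float))
    A, tau = woessner_components(tensor, np.atleast_2d(nh_vector))

    # coarse grid initialisation shared by all models
    s2g = np.linspace(0.05, 1.0, 39)
    tig = np.concatenate([[0.0], np.geomspace(5e-12, _TAU_INT_MAX, 14)])
    reg = np.concatenate([[0.0], np.geomspace(0.25, _REX_MAX / 2, 9)])
    S2m, TIm, REm = np.meshgrid(s2g, tig, reg, indexing="ij")
    pred = _rates_from_components(
        A, tau, S2m[..., None], TIm[..., None], REm[..., None],
        fields_MHz, constants, ref_field_MHz,
    )[..., 0, :, :]
    chi2_grid = np.sum(((pred - obs) / err) ** 2, axis=(-1, -2))

    candidates: dict[str, tuple[np.ndarray, float]] = {}
    model_ids = [force_model] if force_model else list(LOCAL_MODELS)
    # tau_int is carried in ns inside the optimiser so all parameters are O(1)
    bounds_all = {"S2": (0.0, 1.0), "tau_int": (0.0, _TAU_INT_MAX * 1e9), "Rex": (0.0, _REX_MAX)}
    for mid in model_ids:
        names = LOCAL_MODELS[mid]
        sub = chi2_grid.copy()
        if "tau_int" not in names:
            sub = sub[:, :1, :]
        if "Rex" not in names:
            sub = sub[:, :, :1]
        i, j, k = np.unravel_index(np.argmin(sub), sub.shape)
        x0 = {"S2": s2g[i], "tau_int": tig[j] * 1e9, "Rex": reg[k]}
        p0 = np.array([x0[n] for n in names])
        lo = np.array([bounds_all[n][0] for n in names])
        hi = np.array([bounds_all[n][1] for n in names])
        try:
            res = least_squares(
                _local_residuals,
                np.clip(p0, lo + 1e-12, hi - 1e-12),
                bounds=(lo, hi),
                args=(mid, A, tau, obs, err, fields_MHz, constants, ref_field_MHz),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if res.success or res.cost < np.inf:
            candidates[mid] = (res.x, 2.0 * res.cost)
    if not candidates:
        return LocalDynamics(
            residue_id=residue_id, S2=0.5, model_id="failed", flags="no_convergence"
        )
    best = select_model(candidates)
    params, chi2 = candidates[best]
    p = dict(zip(LOCAL_MODELS[best], params))
    return LocalDynamics(
        residue_id=residue_id,
        S2=float(np.clip(p["S2"], 0.0, 1.0)),
        tau_int=float(p.get("tau_int", 0.0)) * 1e-9,
        Rex=float(p.get("Rex", 0.0)),
        model_id=best,
        chi2=float(chi2),
    )


# ---------------------------------------------------------------------------
# global tensor fit
# ---------------------------------------------------------------------------


def _profiled_chi2_factory(vectors, obs, err, fields, constants, ref_field):
    """Return chi2(theta) with (S2, tau_int) profiled out on a grid.

    theta = (log D1, log D2, log D3, gamma_rad).  Rex is held at zero: the
    rigid subset used for tensor determination excludes exchange-broadened
    residues by construction.
    """
    s2g = np.linspace(0.3, 1.0, 57)[:, None, None]  # (ns,1,1)
    tig = np.concatenate([[0.0], np.geomspace(5e-12, 1e-9, 15)])[None, :, None]
    zeros = np.zeros((1, 1, 1))

    def chi2(theta):
        D1, D2, D3 = np.exp(theta[:3])
        tensor = DiffusionTensor(D1, D2, D3, np.rad2deg(theta[3]))
        A, tau = woessner_components(tensor, vectors)
        pred = _rates_from_components(
            A, tau, s2g, tig, zeros, fields, constants, ref_field
        )  # (ns,nt,n,nf,3)
        c = np.sum(((pred - obs) / err) ** 2, axis=(-1, -2))  # (ns,nt,n)
        return float(np.sum(c.min(axis=(0, 1))))

    return chi2


def fit_global_tensor(
    records: pd.DataFrame,
    nh_vectors: Mapping[str, np.ndarray],
    fields_MHz: Sequence[float] = (700.0, 950.0),
    constants: NMRConstants = DEFAULT_CONSTANTS,
    ref_field_MHz: float = 700.0,
    noe_rigid_cutoff: float = 0.65,
    rc_sigma: float = 2.0,
    min_rigid: int = 10,
    n_starts: int = 8,
) -> DiffusionTensor:
    """Fit (D1, D2, D3, gamma) on a rigid residue subset.

    The rigid subset keeps residues with NOE(lower field) above
    ``noe_rigid_cutoff`` and a two-field J(0) consistency ratio within
    ``1 +/- rc_sigma * RC_err`` — i.e. it drops flexible termini and
    exchange-broadened residues, which would otherwise bias the tensor.
    Local (S2, tau_int) are profiled per residue during the search.
    """
    from . import jmap  # deferred: jmap depends only on constants

    fields = sorted(fields_MHz)
    ids, obs, err = _records_to_arrays(records, fields)
    err = _effective_err(obs, err)

    # --- rigid subset rule
    low = fields[0]
    noe_low = {i: obs[n, 0, 2] for n, i in enumerate(ids)}
    rc_tbl = jmap.consistency_table(records, fields, constants, n_mc=200, seed=7)
    rigid = []
    for n, rid in enumerate(ids):
        if noe_low[rid] <= noe_rigid_cutoff:
            continue
        if rid in rc_tbl.index:
            rc, rce = rc_tbl.loc[rid, "RC"], rc_tbl.loc[rid, "RC_err"]
            if np.isfinite(rc) and abs(rc - 1.0) > rc_sigma * max(rce, 5e-3):
                continue
        rigid.append(n)
    if len(rigid) < min_rigid:
        raise ValueError(
            f"only {len(rigid)} rigid residues (< {min_rigid}); "
            "cannot determine the diffusion tensor reliably"
        )
    vecs = np.stack([np.asarray(nh_vectors[ids[n]], float) for n in rigid])
    chi2 = _profiled_chi2_factory(
        vecs, obs[rigid], err[rigid], fields, constants, ref_field_MHz
    )

    # --- isotropic scan for D_iso seed
    tc_grid = np.geomspace(2e-9, 40e-9, 25)
    iso_chi = [chi2(np.array([*np.log([1 / (6 * t)] * 3), 0.0])) for t in tc_grid]
    D0 = 1.0 / (6.0 * tc_grid[int(np.argmin(iso_chi))])

    # --- multi-start Nelder-Mead over (log D, gamma)
    starts = []
    for ratio in (1.0, 1.35):
        for g in (0.0, 45.0, 90.0, 135.0):
            starts.append(
                np.array(
                    [
                        np.log(D0 / ratio ** 0.5),
                        np.log(D0),
                        np.log(D0 * ratio ** 0.5),
                        np.deg2rad(g),
                    ]
                )
            )
    best = None
    for x0 in starts[: max(n_starts, 1)]:
        res = minimize(
            chi2, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):  # pragma: no cover
        raise RuntimeError("tensor fit failed to produce a finite optimum")
    D1, D2, D3 = np.exp(best.x[:3])
    return DiffusionTensor(D1, D2, D3, np.rad2deg(best.x[3])).canonical()


def _refine_tensor(tensor, vectors, S2, tau_int, Rex, obs, err, fields, constants, ref_field):
    """Polish the tensor with locals held fixed (smooth 4-parameter LSQ)."""

    def resid(theta):
        t = DiffusionTensor(*np.exp(theta[:3]), np.rad2deg(theta[3]))
        pred = predict_rates(t, vectors, S2, tau_int, Rex, fields, constants, ref_field)
        return ((pred - obs) / err).ravel()

    x0 = np.array(
        [np.log(tensor.D1), np.log(tensor.D2), np.log(tensor.D3),
         np.deg2rad(tensor.gamma_deg)]
    )
    res = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    D1, D2, D3 = np.exp(res.x[:3])
    return DiffusionTensor(D1, D2, D3, np.rad2deg(res.x[3])), 2.0 * res.cost


# ---------------------------------------------------------------------------
# Monte-Carlo errors
# ---------------------------------------------------------------------------


def monte_carlo_errors(
    model: DynamicsModel,
    records: pd.DataFrame,
    nh_vectors: Mapping[str, np.ndarray],
    n_iter: int = 200,
    constants: NMRConstants = DEFAULT_CONSTANTS,
    seed: int = 20221116,
) -> DynamicsModel:
    """Parameter uncertainties by Gaussian resampling of the observables.

    Each iteration redraws every observable from N(observed, stated error)
    and refits the residue's *selected* local model with the diffusion
    tensor held fixed; the reported error is the standard deviation over
    iterations.  Residues where more than 20% of iterations fail to
    converge are flagged ``mc_unreliable``.
    """
    rng = np.random.default_rng(seed)
    fields = sorted(model.fields_MHz)
    ids, obs, err = _records_to_arrays(records, fields)
    idx = {rid: n for n, rid in enumerate(ids)}
    for rid, ld in model.locals.items():
        if ld.model_id not in LOCAL_MODELS or rid not in idx:
            continue
        n = idx[rid]
        A, tau = woessner_components(model.tensor, np.atleast_2d(nh_vectors[rid]))
        names = LOCAL_MODELS[ld.model_id]
        scale = {"S2": 1.0, "tau_int": 1e9, "Rex": 1.0}  # optimiser carries tau in ns
        p_fit = np.array([getattr(ld, nm) * scale[nm] for nm in names])
        lo = np.array([0.0] * len(names))
        hi = np.array(
            [{"S2": 1.0, "tau_int": _TAU_INT_MAX * 1e9, "Rex": _REX_MAX}[nm] for nm in names]
        )
        draws, failures = [], 0
        for _ in range(n_iter):
            obs_i = rng.normal(obs[n], err[n])
            eff = _effective_err(obs_i, err[n])
            try:
                res = least_squares(
                    _local_residuals,
                    np.clip(p_fit, lo + 1e-12, hi - 1e-12),
                    bounds=(lo, hi),
                    args=(ld.model_id, A, tau, obs_i, eff, fields, constants,
                          model.ref_field_MHz),
                    xtol=1e-10, ftol=1e-10,
                )
            except Exception:  # pragma: no cover
                failures += 1
                continue
            if not np.all(np.isfinite(res.x)):
                failures += 1
                continue
            draws.append(res.x)
        if failures > 0.2 * n_iter:
            ld.flags = (ld.flags + ";" if ld.flags else "") + "mc_unreliable"
        if draws:
            sd = np.std(np.asarray(draws), axis=0, ddof=1)
            for nm, s in zip(names, sd):
                setattr(ld, f"{nm}_err", float(s) / scale[nm])
    return model


# ---------------------------------------------------------------------------
# orchestration / estimator
# ---------------------------------------------------------------------------


class ModelFreeAnalysis(BaseEstimator):
    """Two-field model-free analysis as a scikit-learn style estimator.

    ``fit(records, nh_vectors)`` takes the long-format relaxation table
    (columns ``residue_id, field_MHz, R1, R1_err, R2, R2_err, NOE,
    NOE_err``) and a mapping from residue id to unit N-H vector in the
    C2-aligned molecular frame.  Fitted state:

    ``tensor_`` : DiffusionTensor
    ``locals_`` : dict residue_id -> LocalDynamics
    ``result_`` : DynamicsModel (includes per-residue chi^2 and exclusions)

    Parameters
    ----------
    fields_MHz : tuple
        The two 1H spectrometer frequencies.
    ref_field_MHz : float
        Field at which Rex is reported; Rex scales as (B/B_ref)^2.
    n_mc : int
        Monte-Carlo iterations for parameter errors (0 disables).
    force_model : str or None
        Force one local model (e.g. "M3") instead of AICc selection.
    """

    def __init__(
        self,
        fields_MHz: tuple[float, float] = (700.0, 950.0),
        ref_field_MHz: float = 700.0,
        constants: NMRConstants = DEFAULT_CONSTANTS,
        noe_rigid_cutoff: float = 0.65,
        n_mc: int = 200,
        force_model: str | None = None,
        tol: float = 1e-6,
        max_rounds: int = 20,
        n_starts: int = 8,
        seed: int = 20221116,
    ) -> None:
        self.fields_MHz = fields_MHz
        self.ref_field_MHz = ref_field_MHz
        self.constants = constants
        self.noe_rigid_cutoff = noe_rigid_cutoff
        self.n_mc = n_mc
        self.force_model = force_model
        self.tol = tol
        self.max_rounds = max_rounds
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, records: pd.DataFrame, nh_vectors: Mapping[str, np.ndarray]):
        fields = tuple(sorted(self.fields_MHz))
        ids, obs, err = _records_to_arrays(records, fields)
        if not ids:
            raise ValueError("no residue has a complete two-field record")
        missing = [i for i in ids if i not in nh_vectors]
        excluded = {i: "no N-H vector in structure frame" for i in missing}
        keep = [n for n, i in enumerate(ids) if i not in excluded]
        ids = [ids[n] for n in keep]
        obs, err = obs[keep], err[keep]
        eff = _effective_err(obs, err)
        vecs = np.stack([np.asarray(nh_vectors[i], float) for i in ids])

        tensor = fit_global_tensor(
            records, nh_vectors, fields, self.constants, self.ref_field_MHz,
            self.noe_rigid_cutoff, n_starts=self.n_starts,
        )
        chi2_prev = chi2_now = np.inf
        locals_: dict[str, LocalDynamics] = {}
        for round_ in range(self.max_rounds):
            locals_ = {}
            for n, rid in enumerate(ids):
                locals_[rid] = fit_local(
                    obs[n], err[n], tensor, vecs[n], fields, self.constants,
                    self.ref_field_MHz, residue_id=rid,
                    force_model=self.force_model,
                )
            ok = [n for n, rid in enumerate(ids) if locals_[rid].model_id != "failed"]
            S2 = np.array([locals_[ids[n]].S2 for n in ok])
            ti = np.array([locals_[ids[n]].tau_int for n in ok])
            rex = np.array([locals_[ids[n]].Rex for n in ok])
            tensor, chi2_now = _refine_tensor(
                tensor, vecs[ok], S2, ti, rex, obs[ok], eff[ok], fields,
                self.constants, self.ref_field_MHz,
            )
            if chi2_prev - chi2_now <= self.tol * max(chi2_now, 1e-12):
                break
            chi2_prev = chi2_now
        tensor = tensor.canonical()
        for rid in excluded:
            logger.warning("residue %s excluded: %s", rid, excluded[rid])
        model = DynamicsModel(
            tensor=tensor,
            locals=locals_,
            chi2_global=float(chi2_now),
            ref_field_MHz=self.ref_field_MHz,
            fields_MHz=fields,
            excluded=excluded,
        )
        if self.n_mc > 0:
            model = monte_carlo_errors(
                model, records, nh_vectors, self.n_mc, self.constants, self.seed
            )
        self.tensor_ = tensor
        self.locals_ = locals_
        self.result_ = model
        return self

    def predict(self, nh_vectors: Mapping[str, np.ndarray]) -> pd.DataFrame:
        """Back-calculated (R1, R2, NOE) per residue and field."""
        rows = []
        for rid, ld in self.locals_.items():
            if ld.model_id == "failed" or rid not in nh_vectors:
                continue
            for f in self.result_.fields_MHz:
                r1, r2, noe = predict_observables(
                    self.tensor_, nh_vectors[rid], ld, f, self.constants,
                    self.ref_field_MHz,
                )
                rows.append(
                    {"residue_id": rid, "field_MHz": f, "R1": r1, "R2": r2, "NOE": noe}
                )
        return pd.DataFrame(rows)


def run_mfa(
    records: pd.DataFrame,
    nh_vectors: Mapping[str, np.ndarray],
    **config,
) -> DynamicsModel:
    """Functional wrapper: full tensor + local + MC analysis."""
    est = ModelFreeAnalysis(**config)
    est.fit(records, nh_vectors)
    return est.result_


def segment_mean(values: Mapping[str, float], residues: Sequence[str]) -> tuple[float, float]:
    """Mean +/- sample SD of a per-residue quantity over a segment.

    Mirrors the convention used to report e.g. an average order parameter
    over a secondary-structure element.
    """
    vals = np.array([values[r] for r in residues if r in values], float)
    if vals.size == 0:
        raise ValueError("no segment residue has a value")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd
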