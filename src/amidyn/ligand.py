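"""Ligand-binding analytics from HSQC peak lists and titrations.

Chemical shift perturbations combine the proton and nitrogen shift
changes as ``CSP = sqrt(ddH^2 + 0.1 * ddN^2)`` (ppm).  Fragment-screen
mixtures are ranked by the 7PA statistic — the sum over seven selected
amide proton resonances of |ddH| converted to Hz — with hits above 100 Hz
and strong hits above 300 Hz by default.  Dissociation constants come
from least-squares fits of the 1:1 binding isotherm

.. math:: \\delta_i = \\frac{b - \\sqrt{b^2 - 4ac}}{2a}

with ``a = (Ka/delta_b) [P_t]``, ``b = 1 + Ka([L_ti] + [P_t])``,
``c = delta_b Ka [L_ti]`` — algebraically the fraction of bound protein
times the complex shift ``delta_b`` — fitted per amide and aggregated as
mean +/- SD over amides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_HIT_HZ = 100.0
DEFAULT_STRONG_HZ = 300.0


# ---------------------------------------------------------------------------
# peak lists and CSP
# ---------------------------------------------------------------------------


@dataclass
class PeakList:
    """Assigned amide peak positions for one sample state."""

    state_label: str
    entries: dict[str, tuple[float, float]]  # residue_id -> (dH ppm, dN ppm)
    spectrometer_MHz: float = 600.0

    def __post_init__(self) -> None:
        if self.spectrometer_MHz <= 0:
            raise ValueError("spectrometer frequency must be positive")


_SPARKY_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9]+):)?(?P<res>[A-Z]?\d+)(?:N-H|NH|N-HN)?$")


def read_sparky(path, state_label: str = "", spectrometer_MHz: float = 600.0) -> PeakList:
    """Read a Sparky-style whitespace peak list: ``assignment  w1(N)  w2(H)``."""
    entries: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "Assignment")):
                continue
            parts = line.split()
            if len(parts) < 3:
                continue
            m = _SPARKY_RE.match(parts[0])
            if not m:
                raise ValueError(f"unparseable assignment: {parts[0]!r}")
            rid = m.group("res").lstrip("ACDEFGHIKLMNPQRSTVWY")
            rid = f"{m.group('chain')}:{rid}" if m.group("chain") else rid
            if rid in entries:
                raise ValueError(f"duplicate residue id {rid}")
            w1, w2 = float(parts[1]), float(parts[2])
            entries[rid] = (w2, w1)  # store as (dH, dN)
    return PeakList(state_label or str(path), entries, spectrometer_MHz)


def read_peaklist_tsv(path, state_label: str = "", spectrometer_MHz: float = 600.0) -> PeakList:
    """Read a TSV peak list with columns residue_id, dH_ppm, dN_ppm."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df["residue_id"].duplicated().any():
        raise ValueError("duplicate residue ids in peak list")
    entries = {
        str(r.residue_id): (float(r.dH_ppm), float(r.dN_ppm)) for r in df.itertuples()
    }
    return PeakList(state_label or str(path), entries, spectrometer_MHz)


def csp(delta_H: float, delta_N: float) -> float:
    """Combined chemical shift perturbation (ppm)."""
    return float(np.sqrt(delta_H**2 + 0.1 * delta_N**2))


def csp_profile(free: PeakList, bound: PeakList) -> pd.DataFrame:
    """Per-residue CSP between two assigned states (matched by residue_id)."""
    rows = []
    for rid in sorted(set(free.entries) & set(bound.entries)):
        dH = bound.entries[rid][0] - free.entries[rid][0]
        dN = bound.entries[rid][1] - free.entries[rid][1]
        rows.append(
            {"residue_id": rid, "dH_ppm": dH, "dN_ppm": dN, "csp_ppm": csp(dH, dN)}
        )
    return pd.DataFrame(rows, columns=["residue_id", "dH_ppm", "dN_ppm", "csp_ppm"])


# ---------------------------------------------------------------------------
# screening statistic and triage
# ---------------------------------------------------------------------------


@dataclass
class ScreenRecord:
    """One screening mixture's 7PA result."""

    mixture_id: str
    seven_pa: float  # Hz
    hit_class: str = "none"  # none | hit | strong
    compound_ids: tuple[str, ...] = ()
    compound_conc_uM: float = 500.0
    protein_conc_uM: float = 150.0

    def __post_init__(self) -> None:
        if self.seven_pa < 0:
            raise ValueError("7PA is a sum of magnitudes; must be >= 0")


def seven_pa(free: PeakList, mixed: PeakList, selection: Sequence[str]) -> float:
    """Sum of |amide proton shift changes| over seven residues, in Hz."""
    if len(selection) != 7:
        raise ValueError("the 7PA statistic uses exactly 7 selected residues")
    total = 0.0
    for rid in selection:
        for pl in (free, mixed):
            if rid not in pl.entries:
                raise KeyError(
                    f"selected residue {rid} missing from peak list {pl.state_label!r}"
                )
        ddH = mixed.entries[rid][0] - free.entries[rid][0]
        total += abs(ddH) * free.spectrometer_MHz  # ppm * MHz = Hz
    return float(total)


def classify(seven_pa_hz: float, hit_hz: float = DEFAULT_HIT_HZ,
             strong_hz: float = DEFAULT_STRONG_HZ) -> str:
    if seven_pa_hz > strong_hz:
        return "strong"
    if seven_pa_hz > hit_hz:
        return "hit"
    return "none"


def triage_screen(
    records: Iterable[ScreenRecord],
    library_size: int,
    hit_hz: float = DEFAULT_HIT_HZ,
    strong_hz: float = DEFAULT_STRONG_HZ,
    hits_per_mixture: int = 1,
) -> tuple[pd.DataFrame, int]:
    """Classify mixtures and compute the screen hit rate.

    hit_rate = (number of hit mixtures * assumed hits per mixture) /
    library_size, in percent rounded to the nearest integer.  Returns the
    mixture table ranked by 7PA (for deconvolution) and the hit rate.
    """
    records = list(records)
    seen: set[str] = set()
    for r in records:
        overlap = seen & set(r.compound_ids)
        if overlap:
            import warnings

            warnings.warn(
                f"mixture {r.mixture_id} shares compounds with earlier mixtures: "
                f"{sorted(overlap)}; hit rate still computed per mixture"
            )
        seen |= set(r.compound_ids)
    rows = []
    for r in records:
        r.hit_class = classify(r.seven_pa, hit_hz, strong_hz)
        rows.append(
            {
                "mixture_id": r.mixture_id,
                "seven_pa_hz": r.seven_pa,
                "hit_class": r.hit_class,
                "n_compounds": len(r.compound_ids),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "seven_pa_hz", ascending=False, kind="stable"
    ).reset_index(drop=True)
    n_hits = int((table["hit_class"] != "none").sum())
    hit_rate = int(round(100.0 * n_hits * hits_per_mixture / library_size))
    return table, hit_rate


# ---------------------------------------------------------------------------
# Kd fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TitrationSeries:
    """Per-amide observed shift change versus total ligand concentration."""

    residue_id: str
    P_total: float  # uM
    L_totals: tuple[float, ...]  # uM, strictly increasing, first may be 0
    deltas: tuple[float, ...]  # ppm shift change relative to apo

    def __post_init__(self) -> None:
        L = np.asarray(self.L_totals, float)
        if np.any(L < 0) or np.any(np.diff(L) <= 0):
            raise ValueError("ligand concentrations must be non-negative, increasing")
        if len(self.deltas) != L.size:
            raise ValueError("L_totals and deltas differ in length")
        if L[0] == 0 and self.deltas[0] != 0:
            raise ValueError("shift change at zero ligand must be zero")
        if self.P_total <= 0:
            raise ValueError("protein concentration must be positive")


@dataclass
class KdFit:
    residue_id: str
    Kd: float  # uM
    delta_b: float  # ppm
    Kd_err: float
    delta_b_err: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    flags: str = ""


def binding_isotherm(L_total, Kd: float, delta_b: float, P_total: float):
    """Observed shift change for 1:1 binding (closed-form quadratic root).

    Direct evaluation of the titration equation; equals
    delta_b * [PL]/[P_total] with [PL] the exact 1:1 equilibrium solution.
    """
    L = np.asarray(L_total, float)
    s = P_total + L + Kd
    return delta_b * (s - np.sqrt(s * s - 4.0 * P_total * L)) / (2.0 * P_total)


def equilibrium_bound_fraction(L_total: float, Kd: float, P_total: float) -> float:
    """Brute-force 1:1 equilibrium solver (independent numeric oracle)."""
    if L_total == 0:
        return 0.0
    f = lambda pl: (P_total - pl) * (L_total - pl) - Kd * pl
    pl = brentq(f, 0.0, min(P_total, L_total))
    return pl / P_total


class KdFitter(BaseEstimator, RegressorMixin):
    """Least-squares 1:1 binding fit, scikit-learn style.

    ``fit(L, delta)`` fits (Kd, delta_b) for a fixed total protein
    concentration.  Fitted attributes: ``Kd_``, ``delta_b_``, ``Kd_err_``,
    ``delta_b_err_``, ``flags_``.
    """

    def __init__(self, P_total: float = 250.0) -> None:
        self.P_total = P_total

    def fit(self, L, delta):
        L = np.asarray(L, float).ravel()
        delta = np.asarray(delta, float).ravel()
        nz = L > 0
        if nz.sum() < 3:
            raise ValueError("need at least 3 nonzero-ligand titration points")
        p0 = (float(np.median(L[nz])), float(np.max(np.abs(delta))) or 0.1)
        self.flags_ = ""
        try:
            popt, pcov = curve_fit(
                lambda l, kd, db: binding_isotherm(l, kd, db, self.P_total),
                L, delta, p0=p0, bounds=([1e-6, 1e-9], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"Kd fit did not converge: {exc}") from exc
        perr = np.sqrt(np.diag(pcov))
        if not np.all(np.isfinite(perr)):
            self.flags_ = "poorly_determined"
            perr = np.full(2, np.nan)
        self.Kd_, self.delta_b_ = float(popt[0]), float(popt[1])
        self.Kd_err_, self.delta_b_err_ = float(perr[0]), float(perr[1])
        self.residuals_ = delta - self.predict(L)
        return self

    def predict(self, L):
        return binding_isotherm(L, self.Kd_, self.delta_b_, self.P_total)


def fit_kd(series: TitrationSeries) -> KdFit:
    """Fit one amide's titration; flags fits with singular covariance."""
    est = KdFitter(P_total=series.P_total).fit(series.L_totals, series.deltas)
    return KdFit(
        residue_id=series.residue_id,
        Kd=est.Kd_, delta_b=est.delta_b_,
        Kd_err=est.Kd_err_, delta_b_err=est.delta_b_err_,
        residuals=est.residuals_, flags=est.flags_,
    )


def aggregate_kd(fits: Sequence[KdFit]) -> tuple[float, float, str]:
    """Mean +/- sample SD of per-amide Kd values.

    With a single fit the SD is replaced by that fit's standard error and
    the result is annotated accordingly.
    """
    if not fits:
        raise ValueError("no Kd fits to aggregate")
    kds = np.array([f.Kd for f in fits], float)
    if kds.size == 1:
        return float(kds[0]), float(fits[0].Kd_err), "single_amide_se"
    return float(np.mean(kds)), float(np.std(kds, ddof=1)), ""


def fit_titration_table(
    table: pd.DataFrame,
    P_total: float,
    min_endpoint_csp: float = 0.05,
) -> tuple[list[KdFit], tuple[float, float, str]]:
    """Fit every amide in a titration TSV (residue_id, L_uM, csp_ppm).

    Amides whose endpoint CSP is below ``min_endpoint_csp`` (ppm) are not
    fitted — weakly perturbed amides carry no Kd information.
    """
    fits = []
    for rid, grp in table.groupby("residue_id", sort=True):
        grp = grp.sort_values("L_uM", kind="stable")
        if grp["csp_ppm"].iloc[-1] < min_endpoint_csp:
            continue
        series = TitrationSeries(
            residue_id=str(rid),
            P_total=P_total,
            L_totals=tuple(grp["L_uM"].astype(float)),
            deltas=tuple(grp["csp_ppm"].astype(float)),
        )
        fits.append(fit_kd(series))
    return fits, aggregate_kd(fits)
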