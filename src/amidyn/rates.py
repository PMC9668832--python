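"""Relaxation-rate extraction from peak-intensity decay series.

R1 and R2 are obtained per residue from two-parameter exponential fits
``I(t) = I0 * exp(-R t)`` to peak intensities measured over a schedule of
relaxation delays, with standard errors from the variance-covariance
matrix of the nonlinear least-squares fit.  The heteronuclear NOE is the
ratio of saturated to reference peak intensities, its error propagated
from the two signal-to-noise ratios.  Only residues with the complete
(R1, R2, NOE) set at every field are passed on to model-free analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

# Delay schedules used for the bundled simulations: sixteen R1 delays from
# 0 to 3520 ms and nineteen R2 delays from 0 to 250.16 ms (seconds here).
R1_DELAY_SCHEDULE: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 3.520, 16), 6))
R2_DELAY_SCHEDULE: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 0.25016, 19), 6))


@dataclass(frozen=True)
class DecaySeries:
    """Peak intensity versus relaxation delay for one residue."""

    residue_id: str
    delays: tuple[float, ...]  # seconds
    intensities: tuple[float, ...]
    noise: float  # spectral noise level, same units as intensities

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, float)
        if d.size < 3:
            raise ValueError("a decay series needs at least 3 points")
        if np.any(d < 0):
            raise ValueError("delays must be non-negative")
        if np.any(np.diff(d) < 0):
            raise ValueError("delays must be sorted (duplicates allowed)")
        if len(self.intensities) != d.size:
            raise ValueError("delays and intensities differ in length")
        if not self.noise > 0:
            raise ValueError("noise must be positive")


@dataclass(frozen=True)
class NoePair:
    """Saturated/reference peak intensities for one residue."""

    residue_id: str
    intensity_sat: float
    intensity_ref: float
    snr_sat: float
    snr_ref: float

    def __post_init__(self) -> None:
        if self.intensity_ref == 0:
            raise ValueError("reference intensity must be nonzero")
        if self.snr_sat <= 0 or self.snr_ref <= 0:
            raise ValueError("signal-to-noise values must be positive")


@dataclass
class RelaxationRecord:
    """Complete per-residue, per-field relaxation observables."""

    residue_id: str
    field_MHz: float
    R1: float
    R1_err: float
    R2: float
    R2_err: float
    NOE: float
    NOE_err: float
    flags: str = ""

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError("relaxation rates must be positive")
        if min(self.R1_err, self.R2_err, self.NOE_err) < 0:
            raise ValueError("errors must be non-negative")
        if self.NOE > 1.05:
            raise ValueError("NOE above 1.05 indicates an artefact")


class ExponentialDecayFitter(BaseEstimator, RegressorMixin):
    """Two-parameter exponential decay fit, scikit-learn style.

    ``fit(t, I)`` estimates ``I(t) = I0 * exp(-rate * t)`` by unweighted
    nonlinear least squares.  Fitted attributes: ``rate_``, ``rate_err_``,
    ``amplitude_``, ``amplitude_err_``, ``converged_``.  Standard errors
    come from the variance-covariance matrix.

    Parameters
    ----------
    n_restarts : int
        Random multi-start perturbations tried if the first fit fails.
    seed : int
        Seed for the restart perturbations.
    """

    def __init__(self, n_restarts: int = 5, seed: int = 20221116) -> None:
        self.n_restarts = n_restarts
        self.seed = seed

    @staticmethod
    def _model(t, I0, rate):
        return I0 * np.exp(-rate * t)

    def fit(self, t, I):
        t = np.asarray(t, float).ravel()
        I = np.asarray(I, float).ravel()
        if t.size < 3:
            raise ValueError("need at least 3 decay points")
        if np.allclose(I, I[0]):
            raise ValueError("intensities are all equal; no decay to fit")
        i_min, i_max = np.argmin(t), np.argmax(t)
        span = t[i_max] - t[i_min]
        I0_0 = float(np.max(np.abs(I)))
        with np.errstate(divide="ignore", invalid="ignore"):
            r0 = np.log(np.abs(I[i_min]) / max(np.abs(I[i_max]), 1e-300)) / span
        r0 = float(np.clip(r0, 1e-6, 1e6)) if np.isfinite(r0) else 1.0
        rng = np.random.default_rng(self.seed)
        starts = [(I0_0, r0)]
        starts += [
            (I0_0 * rng.uniform(0.5, 2.0), r0 * rng.uniform(0.2, 5.0))
            for _ in range(self.n_restarts)
        ]
        self.converged_ = False
        for p0 in starts:
            try:
                popt, pcov = curve_fit(
                    self._model, t, I, p0=p0, maxfev=10000,
                    bounds=([-np.inf, 0.0], [np.inf, np.inf]),
                )
            except (RuntimeError, ValueError):
                continue
            if np.all(np.isfinite(popt)) and np.all(np.isfinite(np.diag(pcov))):
                self.amplitude_, self.rate_ = float(popt[0]), float(popt[1])
                perr = np.sqrt(np.diag(pcov))
                self.amplitude_err_, self.rate_err_ = float(perr[0]), float(perr[1])
                self.converged_ = True
                break
        if not self.converged_:
            self.amplitude_ = self.rate_ = np.nan
            self.amplitude_err_ = self.rate_err_ = np.nan
        return self

    def predict(self, t):
        return self._model(np.asarray(t, float), self.amplitude_, self.rate_)


def fit_exponential(series: DecaySeries) -> tuple[float, float, float, bool]:
    """Fit one decay series; returns (rate, I0, rate_err, converged).

    A non-convergent fit (after multi-start restarts) is returned flagged
    rather than silently NaN-filled; callers must check ``converged``.
    """
    est = ExponentialDecayFitter().fit(series.delays, series.intensities)
    return est.rate_, est.amplitude_, est.rate_err_, est.converged_


def compute_noe(pair: NoePair) -> tuple[float, float]:
    """NOE = I_sat / I_ref; error propagated from the two SNR values."""
    noe = pair.intensity_sat / pair.intensity_ref
    err = abs(noe) * np.sqrt(pair.snr_sat**-2 + pair.snr_ref**-2)
    return float(noe), float(err)


def assemble_records(
    rate_fits: Mapping[float, Mapping[str, Mapping[str, tuple[float, float]]]],
    noes: Mapping[float, Mapping[str, tuple[float, float]]],
    fields_MHz: Sequence[float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine per-field R1/R2 fits and NOEs into the record table.

    Parameters
    ----------
    rate_fits : mapping
        ``rate_fits[field]["R1"|"R2"][residue_id] = (rate, err)``.
    noes : mapping
        ``noes[field][residue_id] = (noe, err)``.
    fields_MHz : sequence of float

    Returns
    -------
    records : DataFrame
        Long format, one row per (residue, field); only residues with the
        complete (R1, R2, NOE) set at *every* requested field.
    exclusions : DataFrame
        residue_id and the missing observables that caused exclusion.
    """
    all_ids: set[str] = set()
    for f in fields_MHz:
        for kind in ("R1", "R2"):
            all_ids |= set(rate_fits.get(f, {}).get(kind, {}))
        all_ids |= set(noes.get(f, {}))

    rows, excl = [], []
    for rid in sorted(all_ids):
        missing = []
        for f in fields_MHz:
            for kind in ("R1", "R2"):
                if rid not in rate_fits.get(f, {}).get(kind, {}):
                    missing.append(f"{kind}@{f:g}MHz")
            if rid not in noes.get(f, {}):
                missing.append(f"NOE@{f:g}MHz")
        if missing:
            excl.append({"residue_id": rid, "missing": ";".join(missing)})
            continue
        for f in fields_MHz:
            r1, r1e = rate_fits[f]["R1"][rid]
            r2, r2e = rate_fits[f]["R2"][rid]
            noe, noee = noes[f][rid]
            rows.append(
                {
                    "residue_id": rid, "field_MHz": f,
                    "R1": r1, "R1_err": r1e,
                    "R2": r2, "R2_err": r2e,
                    "NOE": noe, "NOE_err": noee,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(excl, columns=["residue_id", "missing"])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_decay_table(path, noise: float | None = None) -> list[DecaySeries]:
    """Read a long-format TSV/CSV of decay series.

    Columns: ``residue_id, delay_ms, intensity`` and optionally ``noise``
    (constant per residue).  Delays are converted ms -> s here; rates are
    reported in 1/s throughout the package.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    out = []
    for rid, grp in df.groupby("residue_id", sort=True):
        grp = grp.sort_values("delay_ms", kind="stable")
        # replicate delays are legal and fitted jointly
        nz = noise
        if nz is None:
            if "noise" not in grp.columns:
                raise ValueError("no noise column and no noise level given")
            nz = float(grp["noise"].iloc[0])
        out.append(
            DecaySeries(
                residue_id=str(rid),
                delays=tuple(np.asarray(grp["delay_ms"], float) / 1000.0),
                intensities=tuple(np.asarray(grp["intensity"], float)),
                noise=nz,
            )
        )
    return out


def read_noe_table(path) -> list[NoePair]:
    """Read a TSV/CSV with residue_id, intensity_sat, intensity_ref, snr_sat, snr_ref."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    dup = df["residue_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate residue ids: {df['residue_id'][dup].tolist()}")
    return [
        NoePair(str(r.residue_id), float(r.intensity_sat), float(r.intensity_ref),
                float(r.snr_sat), float(r.snr_ref))
        for r in df.itertuples()
    ]


def fit_rate_table(series: Iterable[DecaySeries]) -> dict[str, tuple[float, float]]:
    """Fit every series; non-convergent residues are dropped with a flag."""
    out: dict[str, tuple[float, float]] = {}
    for s in series:
        rate, _, err, ok = fit_exponential(s)
        if ok:
            out[s.residue_id] = (rate, err)
    return out


def write_records(records: pd.DataFrame, path) -> None:
    """Write the record table as TSV with a unit header comment."""
    with open(path, "w") as fh:
        fh.write("# R1, R2 in 1/s; NOE dimensionless; field in MHz (1H)\n")
        records.to_csv(fh, sep="\t", index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
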