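"""Reduced spectral density mapping and two-field consistency testing.

From one field's (R1, R2, NOE) the spectral density of the N-H vector is
estimated at three frequencies using the standard single high-frequency
reduction:

.. math::

    \\sigma_{NH} &= R_1 (\\mathrm{NOE} - 1) \\gamma_N / \\gamma_H \\\\
    J(0.87\\omega_H) &= \\sigma_{NH} / (5 d^2/4) \\\\
    J(\\omega_N) &= \\frac{R_1 - 7 (d^2/4) J(0.87\\omega_H)}{3 d^2/4 + c^2} \\\\
    J(0)_{app} &= \\frac{R_2 - \\tfrac{d^2}{8}(13 J(0.87\\omega_H) + 3 J(\\omega_N))
                 - \\tfrac{c^2}{2} J(\\omega_N)}{\\tfrac{d^2}{2} + \\tfrac{2}{3} c^2}

Any exchange contribution Rex inflates the *apparent* J(0), and because
Rex grows with the square of the static field while the true J(0) does
not, the per-residue ratio of apparent J(0) between a higher and a lower
field — the residue consistency ratio RC — sits at 1 for exchange-free
residues and rises above 1 where us-ms exchange is present.  Errors are
propagated by Monte-Carlo resampling of the observables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, NMRConstants

NOE_MAX = 1.05  # tolerance above the theoretical maximum; beyond it -> artefact


@dataclass
class SpectralDensityMap:
    """Per-residue J(0), J(omega_N), J(0.87 omega_H) at one field (s/rad)."""

    residue_id: str
    field_MHz: float
    J0: float
    JwN: float
    JwH087: float
    J0_err: float = 0.0
    JwN_err: float = 0.0
    JwH087_err: float = 0.0
    flags: str = ""


@dataclass
class ConsistencyRatio:
    """High-field over low-field apparent J(0); > 1 flags us-ms exchange."""

    residue_id: str
    RC: float
    RC_err: float = 0.0
    exchange: bool = False
    flags: str = ""


def _map_arrays(R1, R2, NOE, field_MHz: float, constants: NMRConstants):
    """Vectorised reduced mapping; returns (J0_app, JwN, JwH087)."""
    D = constants.d2 / 4.0
    C = constants.c2(field_MHz)
    sigma = R1 * (NOE - 1.0) * (constants.gamma_N / constants.gamma_H)
    JH = sigma / (5.0 * D)
    JN = (R1 - 7.0 * D * JH) / (3.0 * D + C)
    J0 = (R2 - (D / 2.0) * (13.0 * JH + 3.0 * JN) - (C / 2.0) * JN) / (
        2.0 * D + (2.0 / 3.0) * C
    )
    return J0, JN, JH


def reduced_spectral_density(
    record,
    constants: NMRConstants = DEFAULT_CONSTANTS,
    n_mc: int = 1000,
    seed: int = 20221116,
) -> SpectralDensityMap:
    """Map one residue's (R1, R2, NOE) at one field to J(0), J(wN), J(0.87wH).

    ``record`` is anything with attributes/keys ``residue_id, field_MHz,
    R1, R1_err, R2, R2_err, NOE, NOE_err`` (a :class:`RelaxationRecord`
    or a DataFrame row).  Errors come from ``n_mc`` Gaussian draws of the
    observables around their stated uncertainties.
    """
    get = (lambda k: record[k]) if hasattr(record, "__getitem__") else (
        lambda k: getattr(record, k)
    )
    field = float(get("field_MHz"))
    if field <= 0:
        raise ValueError("field_MHz must be positive")
    R1, R2, NOE = (float(get(k)) for k in ("R1", "R2", "NOE"))
    errs = np.array([float(get(k + "_err")) for k in ("R1", "R2", "NOE")])
    flags = []
    if NOE > NOE_MAX:
        flags.append("noe_above_max")
    J0, JN, JH = _map_arrays(R1, R2, NOE, field, constants)

    rng = np.random.default_rng(seed)
    draws = rng.normal([R1, R2, NOE], errs, size=(max(n_mc, 2), 3))
    J0s, JNs, JHs = _map_arrays(draws[:, 0], draws[:, 1], draws[:, 2], field, constants)
    e0, eN, eH = (float(np.std(a, ddof=1)) for a in (J0s, JNs, JHs))
    for val, errv, name in ((J0, e0, "J0"), (JN, eN, "JwN"), (JH, eH, "JwH087")):
        if val < -errv:
            flags.append(f"negative_{name}")
    return SpectralDensityMap(
        residue_id=str(get("residue_id")),
        field_MHz=field,
        J0=float(J0), JwN=float(JN), JwH087=float(JH),
        J0_err=e0, JwN_err=eN, JwH087_err=eH,
        flags=";".join(flags),
    )


def consistency_ratio(
    map_high: SpectralDensityMap,
    map_low: SpectralDensityMap,
    rc_sigma: float = 3.0,
) -> ConsistencyRatio:
    """RC = J(0)_app(high field) / J(0)_app(low field) for one residue.

    The error combines the two (independent) J(0) uncertainties; the
    residue is flagged as exchanging when RC - 1 exceeds
    ``rc_sigma * RC_err``.
    """
    if map_high.residue_id != map_low.residue_id:
        raise ValueError("consistency ratio requires maps of the same residue")
    if map_high.field_MHz <= map_low.field_MHz:
        raise ValueError("map_high must be the higher-field map")
    if map_low.J0 <= 0:
        return ConsistencyRatio(
            residue_id=map_low.residue_id, RC=np.nan, RC_err=np.nan,
            flags="nonpositive_low_field_J0",
        )
    rc = map_high.J0 / map_low.J0
    rc_err = abs(rc) * np.sqrt(
        (map_high.J0_err / map_high.J0) ** 2 + (map_low.J0_err / map_low.J0) ** 2
    ) if map_high.J0 != 0 else np.nan
    return ConsistencyRatio(
        residue_id=map_low.residue_id,
        RC=float(rc),
        RC_err=float(rc_err),
        exchange=bool(rc - 1.0 > rc_sigma * rc_err),
    )


def jmap_table(
    records: pd.DataFrame,
    constants: NMRConstants = DEFAULT_CONSTANTS,
    n_mc: int = 1000,
    seed: int = 20221116,
) -> pd.DataFrame:
    """Reduced mapping for every (residue, field) row of a record table."""
    rows = []
    for k, (_, rec) in enumerate(records.iterrows()):
        m = reduced_spectral_density(rec, constants, n_mc, seed + k)
        rows.append(vars(m))
    return pd.DataFrame(rows)


def consistency_table(
    records: pd.DataFrame,
    fields_MHz: Sequence[float] = (700.0, 950.0),
    constants: NMRConstants = DEFAULT_CONSTANTS,
    n_mc: int = 1000,
    seed: int = 20221116,
    rc_sigma: float = 3.0,
) -> pd.DataFrame:
    """Per-residue RC table from a two-field record table.

    Returns a DataFrame indexed by residue_id with columns
    ``RC, RC_err, exchange, flags`` plus the per-field J(0) values.
    """
    lo, hi = sorted(fields_MHz)
    jm = jmap_table(records, constants, n_mc, seed)
    rows = []
    for rid, grp in jm.groupby("residue_id"):
        glo = grp[np.isclose(grp["field_MHz"], lo)]
        ghi = grp[np.isclose(grp["field_MHz"], hi)]
        if len(glo) != 1 or len(ghi) != 1:
            continue
        mlo = SpectralDensityMap(**glo.iloc[0].to_dict())
        mhi = SpectralDensityMap(**ghi.iloc[0].to_dict())
        rc = consistency_ratio(mhi, mlo, rc_sigma)
        rows.append(
            {
                "residue_id": rid,
                "RC": rc.RC,
                "RC_err": rc.RC_err,
                "exchange": rc.exchange,
                "J0_low": mlo.J0, "J0_low_err": mlo.J0_err,
                "J0_high": mhi.J0, "J0_high_err": mhi.J0_err,
                "flags": ";".join(x for x in (mlo.flags, mhi.flags, rc.flags) if x),
            }
        )
    return pd.DataFrame(rows).set_index("residue_id").sort_index()
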