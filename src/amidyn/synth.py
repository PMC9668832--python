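"""Synthetic data generation for every stage of the pipeline.

All generators are pure functions of (parameters, seed) and emit exactly
the objects/tables the analysis modules consume, together with a truth
manifest, so parameter-recovery can be scored end to end.  The defaults
mirror the measurement setup the analyses are designed for: two-field
(700/950 MHz) relaxation of a C2-symmetric homodimer, sixteen R1 delays
to 3.52 s and nineteen R2 delays to 250.16 ms, four-point titrations at
125/250/500/1000 uM ligand against 250 uM protein, and screening
mixtures of 10 compounds at 500 uM each.

The relaxation noise model is 2% Gaussian noise on peak intensities by
default; rate uncertainties then arise the same way they do for measured
data — from the variance-covariance matrix of the exponential fits — and
NOE uncertainties from the synthetic signal-to-noise ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from . import ligand, rates
from .constants import DEFAULT_CONSTANTS, NMRConstants
from .mfa import DiffusionTensor, predict_rates
from .rates import R1_DELAY_SCHEDULE, R2_DELAY_SCHEDULE, DecaySeries, ExponentialDecayFitter
from .structmap import construct_amide_H

DEFAULT_FIELDS = (700.0, 950.0)
DEFAULT_NOISE_FRAC = 0.02
DEFAULT_L_SCHEDULE = (125.0, 250.0, 500.0, 1000.0)  # uM, tight binders
WEAK_BINDER_L_SCHEDULE = (250.0, 500.0, 1000.0, 2000.0)  # uM, Kd >~ 400 uM
DEFAULT_MIXTURE_SIZE = 10
DEFAULT_COMPOUND_CONC = 500.0  # uM


@dataclass
class GroundTruth:
    """Planted global and local dynamics parameters.

    ``locals`` maps residue_id -> (S2, tau_int [s], Rex [1/s at the
    reference field]); ``vectors`` maps residue_id -> unit N-H vector in
    the C2-aligned molecular frame.
    """

    tensor: DiffusionTensor
    locals: dict[str, tuple[float, float, float]]
    vectors: dict[str, np.ndarray]
    fields_MHz: tuple[float, float] = DEFAULT_FIELDS
    ref_field_MHz: float = 700.0
    noise_frac: float = DEFAULT_NOISE_FRAC
    seed: int = 20221116

    def manifest(self) -> pd.DataFrame:
        rows = []
        for rid, (s2, ti, rex) in self.locals.items():
            v = self.vectors[rid]
            rows.append(
                {"residue_id": rid, "S2": s2, "tau_int": ti, "Rex": rex,
                 "vx": v[0], "vy": v[1], "vz": v[2], "seed": self.seed}
            )
        return pd.DataFrame(rows)


def random_unit_vectors(n: int, seed: int = 20221116) -> np.ndarray:
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def default_ground_truth(
    n_residues: int = 60,
    tensor: DiffusionTensor | None = None,
    rex_fraction: float = 1.0 / 3.0,
    seed: int = 20221116,
    noise_frac: float = DEFAULT_NOISE_FRAC,
) -> GroundTruth:
    """The standard synthetic dimer: planted tensor with anisotropy ~1.6
    and gamma = 35 deg, S2 in [0.5, 0.98], tau_int in [20, 200] ps, and a
    third of the residues carrying Rex in [2, 6] 1/s.

    S2 is drawn as a folded-protein mixture — three quarters of residues
    form a well-ordered core (S2 in [0.85, 0.98]) and one quarter are
    loop-like (S2 in [0.5, 0.85]) — matching how order parameters
    distribute in a compact homodimer rather than uniformly filling the
    range.
    """
    if tensor is None:
        tensor = DiffusionTensor(1.2e7, 1.4e7, 1.9e7, 35.0)
    rng = np.random.default_rng(seed)
    vecs = random_unit_vectors(n_residues, seed + 1)
    locals_: dict[str, tuple[float, float, float]] = {}
    vectors: dict[str, np.ndarray] = {}
    n_rex = int(round(rex_fraction * n_residues))
    rex_idx = set(rng.choice(n_residues, size=n_rex, replace=False).tolist())
    for i in range(n_residues):
        rid = f"A:{i + 1}"
        if rng.random() < 0.75:
            s2 = float(rng.uniform(0.85, 0.98))
        else:
            s2 = float(rng.uniform(0.5, 0.85))
        ti = float(rng.uniform(20e-12, 200e-12))
        rex = float(rng.uniform(2.0, 6.0)) if i in rex_idx else 0.0
        locals_[rid] = (s2, ti, rex)
        vectors[rid] = vecs[i]
    return GroundTruth(tensor=tensor, locals=locals_, vectors=vectors,
                       seed=seed, noise_frac=noise_frac)


# ---------------------------------------------------------------------------
# relaxation observables
# ---------------------------------------------------------------------------


def _noiseless_rates(truth: GroundTruth, constants: NMRConstants) -> pd.DataFrame:
    ids = sorted(truth.locals, key=lambda r: (r.split(":")[0], int(r.split(":")[-1])))
    vecs = np.stack([truth.vectors[r] for r in ids])
    s2 = np.array([truth.locals[r][0] for r in ids])
    ti = np.array([truth.locals[r][1] for r in ids])
    rex = np.array([truth.locals[r][2] for r in ids])
    obs = predict_rates(truth.tensor, vecs, s2, ti, rex, truth.fields_MHz,
                        constants, truth.ref_field_MHz)
    rows = []
    for i, rid in enumerate(ids):
        for j, f in enumerate(truth.fields_MHz):
            r1, r2, noe = obs[i, j]
            rows.append({"residue_id": rid, "field_MHz": f,
                         "R1": r1, "R2": r2, "NOE": noe})
    return pd.DataFrame(rows)


def simulate_observables(
    truth: GroundTruth,
    noise_frac: float | None = None,
    via_decay: bool = False,
    constants: NMRConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Two-field (R1, R2, NOE) records from the forward model.

    ``noise_frac`` (default: ``truth.noise_frac``) is the Gaussian noise
    level as a fraction of the reference peak intensity.  With
    ``via_decay=True`` each rate is obtained by actually simulating the
    intensity decay at the standard delay schedule and refitting it, so
    the stated rate errors are covariance-derived exactly as for measured
    data; otherwise the fractional noise is applied to the rates directly
    (errors stated as the true sigma).  NOE noise always goes through the
    saturated/reference intensity ratio.  Zero noise returns the forward
    model exactly, with zero errors.
    """
    f = truth.noise_frac if noise_frac is None else noise_frac
    clean = _noiseless_rates(truth, constants)
    rng = np.random.default_rng(truth.seed)
    rows = []
    for _, rec in clean.iterrows():
        r1, r2, noe = rec["R1"], rec["R2"], rec["NOE"]
        if f == 0:
            rows.append({**rec, "R1_err": 0.0, "R2_err": 0.0, "NOE_err": 0.0})
            continue
        if via_decay:
            r1, r1e = _rate_via_decay(r1, R1_DELAY_SCHEDULE, f, rng)
            r2, r2e = _rate_via_decay(r2, R2_DELAY_SCHEDULE, f, rng)
        else:
            r1e, r2e = f * r1, f * r2
            r1, r2 = rng.normal(r1, r1e), rng.normal(r2, r2e)
        # NOE via the intensity-ratio path with SNR = 1/f on the reference
        sat = rng.normal(noe, f)
        ref = rng.normal(1.0, f)
        pair = rates.NoePair("x", sat, ref, snr_sat=max(abs(noe), 1e-3) / f,
                             snr_ref=1.0 / f)
        noe, noee = rates.compute_noe(pair)
        rows.append({"residue_id": rec["residue_id"], "field_MHz": rec["field_MHz"],
                     "R1": r1, "R1_err": r1e, "R2": r2, "R2_err": r2e,
                     "NOE": noe, "NOE_err": noee})
    return pd.DataFrame(rows)


def _rate_via_decay(rate: float, schedule: Sequence[float], noise_frac: float,
                    rng: np.random.Generator, I0: float = 100.0) -> tuple[float, float]:
    t = np.asarray(schedule)
    I = I0 * np.exp(-rate * t) + rng.normal(0.0, noise_frac * I0, size=t.size)
    est = ExponentialDecayFitter(seed=int(rng.integers(2**31))).fit(t, I)
    return est.rate_, est.rate_err_


def simulate_decay_series(
    truth: GroundTruth,
    noise_frac: float | None = None,
    I0: float = 100.0,
    constants: NMRConstants = DEFAULT_CONSTANTS,
) -> dict[float, dict[str, dict[str, DecaySeries]]]:
    """Expand R1/R2 into intensity decay series: out[field][kind][residue]."""
    f = truth.noise_frac if noise_frac is None else noise_frac
    clean = _noiseless_rates(truth, constants)
    rng = np.random.default_rng(truth.seed + 17)
    out: dict[float, dict[str, dict[str, DecaySeries]]] = {}
    for _, rec in clean.iterrows():
        fld = float(rec["field_MHz"])
        out.setdefault(fld, {"R1": {}, "R2": {}})
        for kind, schedule in (("R1", R1_DELAY_SCHEDULE), ("R2", R2_DELAY_SCHEDULE)):
            t = np.asarray(schedule)
            I = I0 * np.exp(-rec[kind] * t)
            if f > 0:
                I = I + rng.normal(0.0, f * I0, size=t.size)
            out[fld][kind][rec["residue_id"]] = DecaySeries(
                residue_id=rec["residue_id"], delays=tuple(t),
                intensities=tuple(I), noise=max(f * I0, 1e-9),
            )
    return out


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------


def simulate_titration(
    Kd: float,
    delta_b: Mapping[str, float],
    P_total: float = 250.0,
    L_schedule: Sequence[float] = DEFAULT_L_SCHEDULE,
    noise_frac: float = 0.0,
    seed: int = 20221116,
) -> dict[str, ligand.TitrationSeries]:
    """Per-amide 1:1-binding titration curves (plus the L = 0 anchor).

    Multiplicative Gaussian noise of ``noise_frac`` (fraction of each
    point's value) is added to the nonzero-ligand points.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for rid, db in delta_b.items():
        L = np.asarray(L_schedule, float)
        d = ligand.binding_isotherm(L, Kd, db, P_total)
        if noise_frac > 0:
            d = d * (1.0 + rng.normal(0.0, noise_frac, size=L.size))
        out[rid] = ligand.TitrationSeries(
            residue_id=rid, P_total=P_total,
            L_totals=(0.0, *L), deltas=(0.0, *np.abs(d)),
        )
    return out


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def simulate_screen(
    library_size: int = 600,
    mixtures_of: int = DEFAULT_MIXTURE_SIZE,
    n_planted_mixtures: int = 40,
    n_residues: int = 100,
    selection_size: int = 7,
    effect_ppm: tuple[float, float] = (0.04, 0.12),
    noise_ppm: float = 0.0,
    spectrometer_MHz: float = 600.0,
    compound_conc_uM: float = DEFAULT_COMPOUND_CONC,
    seed: int = 20221116,
):
    """A fragment screen with planted binder-containing mixtures.

    The library is partitioned into mixtures of ``mixtures_of`` compounds;
    ``n_planted_mixtures`` of them contain one binder each, which shifts
    the selected reporter amide protons by |ddH| drawn uniformly from
    ``effect_ppm``.  All peaks additionally jitter by ``noise_ppm``.

    Returns ``(free, mixed, selection, manifest)``: the apo peak list, a
    dict mixture_id -> perturbed peak list, the reporter residue ids, and
    a manifest DataFrame recording composition and planted truth.
    """
    if library_size % mixtures_of:
        raise ValueError("library_size must be a multiple of the mixture size")
    n_mix = library_size // mixtures_of
    if n_planted_mixtures > n_mix:
        raise ValueError("more planted mixtures than mixtures")
    rng = np.random.default_rng(seed)
    entries = {
        str(i + 1): (float(rng.uniform(6.5, 10.5)), float(rng.uniform(105.0, 130.0)))
        for i in range(n_residues)
    }
    free = ligand.PeakList("free", entries, spectrometer_MHz)
    selection = [str(r + 1) for r in rng.choice(n_residues, selection_size, replace=False)]

    planted = set(rng.choice(n_mix, size=n_planted_mixtures, replace=False).tolist())
    mixed: dict[str, ligand.PeakList] = {}
    rows = []
    for m in range(n_mix):
        mid = f"mix{m + 1:03d}"
        compounds = tuple(f"C{m * mixtures_of + k + 1:04d}" for k in range(mixtures_of))
        pe = {}
        shifts = {}
        if m in planted:
            for rid in selection:
                mag = float(rng.uniform(*effect_ppm))
                shifts[rid] = mag * (1 if rng.random() < 0.5 else -1)
        for rid, (h, n) in entries.items():
            dh = shifts.get(rid, 0.0)
            if noise_ppm > 0:
                dh += float(rng.normal(0.0, noise_ppm))
                n = n + float(rng.normal(0.0, noise_ppm * 5))
            pe[rid] = (h + dh, n)
        mixed[mid] = ligand.PeakList(mid, pe, spectrometer_MHz)
        rows.append({"mixture_id": mid, "compound_ids": ";".join(compounds),
                     "compound_conc_uM": compound_conc_uM,
                     "binder": compounds[0] if m in planted else ""})
    manifest = pd.DataFrame(rows)
    return free, mixed, selection, manifest


# ---------------------------------------------------------------------------
# toy dimer structure
# ---------------------------------------------------------------------------

_GEOM = {  # bond lengths (A) and angles (deg) of an ideal peptide backbone
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329,
    "C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.6,
    "phi": -57.0, "psi": -47.0, "omega": 180.0,
}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates (distance to c, angle b-c-d,
    dihedral a-b-c-d)."""
    theta, phi = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    bc = (c - b) / np.linalg.norm(c - b)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = r * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _helical_chain(n_residues: int) -> list[dict[str, np.ndarray]]:
    g = _GEOM
    res: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([g["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(g["N-CA-C"])
    C = CA + g["CA-C"] * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    res.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n_residues):
        p = res[-1]
        N = _nerf(p["N"], p["CA"], p["C"], g["C-N"], g["CA-C-N"], g["psi"])
        CA = _nerf(p["CA"], p["C"], N, g["N-CA"], g["C-N-CA"], g["omega"])
        C = _nerf(p["C"], N, CA, g["CA-C"], g["N-CA-C"], g["phi"])
        cur = {"N": N, "CA": CA, "C": C}
        cur["H"] = construct_amide_H(N, CA, p["C"])
        res.append(cur)
    return res


def make_toy_dimer(n_residues_per_chain: int = 12, offset: float = 12.0) -> gemmi.Structure:
    """Miniature two-chain structure with exact C2 symmetry about z.

    Chain A is an ideal helix displaced ``offset`` A along +x; chain B is
    chain A rotated by exactly 180 degrees about the z axis.
    """
    if n_residues_per_chain < 3:
        raise ValueError("need at least 3 residues per chain")
    chain_a = _helical_chain(n_residues_per_chain)
    shift = np.array([offset, 0.0, 0.0])
    Rz = np.diag([-1.0, -1.0, 1.0])  # 180 deg about z

    st = gemmi.Structure()
    st.name = "toy_c2_dimer"
    model = gemmi.Model("1")
    for cname, transform in (("A", lambda x: x + shift),
                             ("B", lambda x: Rz @ (x + shift))):
        chain = gemmi.Chain(cname)
        for i, atoms in enumerate(chain_a):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            for name, pos in atoms.items():
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(name[0])
                at.occ = 1.0
                at.b_iso = 0.0
                at.pos = gemmi.Position(*transform(pos))
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st
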