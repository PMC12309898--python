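"""ASE qBOLD and gradient-echo BOLD signal models.

Two forward routes are provided:

* an analytic static-dephasing model (no water diffusion), piecewise in the
  spin-echo displacement time tau: a quadratic short-tau regime and the
  linear long-tau regime ``ln S(tau) = ln S(0) + DBV - R2' tau``;
* a Monte Carlo vascular dephasing simulator: protons random-walk around
  randomly oriented cylinders, giving the diffusion-sensitive signal that the
  static-dephasing estimators are then applied to.

The Monte Carlo route is accelerated by caching per-radius phase tables at a
small reference volume fraction: phases rescale exactly with susceptibility
(hematocrit and oxygen saturation), and log-attenuations rescale linearly
with volume fraction in the dilute-vessel limit.  ASE grids are simulated on
a 4-ms tau raster and gradient-echo grids on a 2-ms TE raster, then linearly
interpolated to the requested protocol times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import j0, roots_legendre

from . import _cylinder_mc
from .physiology import BloodGasConstants, PhysiologicalState, hyperoxia_pair

__all__ = [
    "GAMMA",
    "DCHI0",
    "AseProtocol",
    "BoldProtocol",
    "TrustProtocol",
    "VesselPopulation",
    "SignalCurve",
    "r2p_static_dephasing",
    "static_dephasing_fc",
    "ase_signal_analytic",
    "mc_single_radius",
    "mc_combine",
    "delta_bold_forward",
    "MonteCarloForward",
]

GAMMA = 2.675e8  # proton gyromagnetic ratio, rad s^-1 T^-1
DCHI0 = 0.264e-6  # susceptibility difference per unit Hct, fully deoxy vs oxy RBCs

_DEFAULT_TAUS = tuple(float(t) for t in range(0, 67, 3))


@dataclass(frozen=True)
class AseProtocol:
    """Asymmetric-spin-echo acquisition timing (times in ms, TR in s)."""

    te: float = 80.0
    taus: tuple[float, ...] = _DEFAULT_TAUS
    tr: float = 3.0

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        if taus.size == 0 or np.any(taus < 0) or np.any(np.diff(taus) <= 0):
            raise ValueError("taus must be non-negative and strictly increasing")
        if self.te <= taus[-1]:
            raise ValueError("te must exceed the largest tau")


@dataclass(frozen=True)
class BoldProtocol:
    """Gradient-echo BOLD acquisition timing (TE in ms, TR in s)."""

    te: float = 35.0
    tr: float = 1.0
    n_volumes: int = 600

    def __post_init__(self) -> None:
        if self.te <= 0 or self.tr <= 0 or self.n_volumes <= 0:
            raise ValueError("te, tr and n_volumes must be positive")


@dataclass(frozen=True)
class TrustProtocol:
    """TRUST venous-oximetry acquisition: T2-preparation times and repeats."""

    etes: tuple[float, ...] = (0.0, 40.0, 80.0, 160.0)
    n_repeats: int = 4

    def __post_init__(self) -> None:
        if len(self.etes) < 2 or self.n_repeats < 1:
            raise ValueError("need >= 2 eTEs and >= 1 repeat")


@dataclass(frozen=True)
class VesselPopulation:
    """Vessel compartments as (radius um, volume fraction, O2 saturation)."""

    compartments: tuple[tuple[float, float, float], ...]
    diffusion_coeff: float = 1.0  # um^2 ms^-1
    field_b0: float = 3.0  # T
    dchi0: float = DCHI0
    gamma: float = GAMMA

    def __post_init__(self) -> None:
        total = 0.0
        for radius, vf, sat in self.compartments:
            if radius <= 0:
                raise ValueError("vessel radii must be positive")
            if not 0 <= vf <= 1 or not 0 <= sat <= 1:
                raise ValueError("volume fractions and saturations lie in [0, 1]")
            total += vf
        if total > 1:
            raise ValueError("compartment volume fractions must sum to <= 1")


@dataclass
class SignalCurve:
    """A sampled signal curve over a tau or TE grid (ms)."""

    abscissa: np.ndarray
    attenuation: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        """Write the curve as TSV with the metadata in a `# key=value` header."""
        lines = []
        for key, val in self.meta.items():
            if isinstance(val, (int, float, str, bool)):
                lines.append(f"# {key}={val}")
        lines.append("abscissa\tattenuation")
        for x, a in zip(self.abscissa, self.attenuation):
            lines.append(f"{x:.10g}\t{a:.12g}")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "SignalCurve":
        from pathlib import Path

        meta: dict = {}
        xs, ys = [], []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                try:
                    meta[key] = float(val)
                except ValueError:
                    meta[key] = val
            elif line and not line.startswith("abscissa"):
                x, y = line.split("\t")
                xs.append(float(x))
                ys.append(float(y))
        return cls(np.array(xs), np.array(ys), meta)


def r2p_static_dephasing(
    oef, hct, dbv, field: float = 3.0, dchi0: float = DCHI0, gamma: float = GAMMA
):
    """Reversible relaxation rate R2' (s^-1) in the static-dephasing regime.

    R2' = gamma (4/3) pi dchi0 Hct OEF B0 DBV; linear in every argument.
    """
    oef = np.asarray(oef, dtype=float)
    out = gamma * (4.0 / 3.0) * np.pi * dchi0 * hct * oef * field * dbv
    return float(out) if out.ndim == 0 else out


def characteristic_frequency(
    desaturation, hct, field: float = 3.0, dchi0: float = DCHI0, gamma: float = GAMMA
):
    """Characteristic dephasing frequency delta-omega (s^-1) of a compartment.

    ``desaturation`` is 1 - Y of the blood in the compartment; R2' of the
    compartment in the static regime is its volume fraction times this rate.
    """
    return gamma * (4.0 / 3.0) * np.pi * dchi0 * hct * desaturation * field


_FC_NODES, _FC_WEIGHTS = roots_legendre(160)
_FC_X = 0.5 * (_FC_NODES + 1.0)  # map to (0, 1)
_FC_W = 0.5 * _FC_WEIGHTS


def static_dephasing_fc(u):
    """Dimensionless static-dephasing decay function fc(u).

    ``ln S(t) = -DBV * fc(dw * t)`` for a random cylinder suspension; behaves
    as 0.3 u^2 for small u and as u - 1 for large u.  Evaluated by fixed
    Gauss-Legendre quadrature of the isotropic-cylinder average.
    """
    u = np.asarray(u, dtype=float)
    x = _FC_X
    core = (2.0 + x) * np.sqrt(1.0 - x) / (3.0 * x**2)
    vals = np.einsum(
        "k,k,...k->...", _FC_W, core, 1.0 - j0(1.5 * np.multiply.outer(u, x))
    )
    return float(vals) if vals.ndim == 0 else vals


def ase_signal_analytic(
    state: PhysiologicalState,
    protocol: AseProtocol = AseProtocol(),
    ln_s0_minus_te_r2: float = 0.0,
    field: float = 3.0,
    tau_transition: float = 15.0,
) -> SignalCurve:
    """Noiseless static-dephasing ASE signal for one physiological state.

    Single (venous) compartment model with the two-regime structure used by
    the linear-system estimator: for tau > ``tau_transition``
    ``ln S = offset + DBV - R2' tau`` and for 0 < tau <= ``tau_transition``
    the quadratic short-tau regime ``ln S = offset - 0.3 DBV (R2' tau/DBV)^2``
    (at tau = 0, ln S = offset exactly).
    """
    r2p = r2p_static_dephasing(state.oef, state.hct, state.dbv, field)
    return _two_regime_curve(
        np.asarray(protocol.taus, dtype=float),
        r2p,
        state.dbv,
        ln_s0_minus_te_r2,
        tau_transition,
        meta={"state": state, "protocol": protocol, "model": "analytic"},
    )


def _two_regime_curve(taus, r2p, dbv, offset, tau_transition, meta=None):
    tau_s = taus * 1e-3
    ln_s = np.full_like(tau_s, offset)
    long_mask = taus > tau_transition
    ln_s[long_mask] += dbv - r2p * tau_s[long_mask]
    short = (taus > 0) & ~long_mask
    if dbv > 0:
        dw = r2p / dbv  # characteristic frequency, s^-1
        ln_s[short] -= 0.3 * dbv * (dw * tau_s[short]) ** 2
    return SignalCurve(taus.copy(), np.exp(ln_s), meta or {})


# ---------------------------------------------------------------------------
# Monte Carlo route


@dataclass
class PhaseTable:
    """Cached per-radius proton phase trajectories at unit susceptibility."""

    radius: float
    times: np.ndarray  # checkpoint times, ms
    phases: np.ndarray  # (n_extravascular_protons, n_times), rad per unit dchi
    vf_ref: float
    total_time: float
    n_protons: int
    seed: int
    diffusion_coeff: float
    dt: float

    def column(self, t: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise ValueError(f"time {t} ms not in simulated checkpoint grid")
        return self.phases[:, idx[0]]


_TABLE_CACHE: dict[tuple, PhaseTable] = {}


def build_phase_table(
    radius: float,
    n_protons: int = 10_000,
    seed: int = 0,
    diffusion_coeff: float = 1.0,
    dt: float = 0.1,
    vf_ref: float = 0.03,
    rs_factor: float = 30.0,
    field: float = 3.0,
    total_time: float = 80.0,
    gamma: float = GAMMA,
    cache: bool = True,
) -> PhaseTable:
    """Simulate (or fetch from cache) the phase table for one vessel radius.

    Checkpoints are every 2 ms up to ``total_time``, which supports any ASE
    tau on a 4-ms raster (refocusing at (TE - tau)/2) and any gradient-echo
    TE on a 2-ms raster.  Intravascular protons are dropped from the table
    (the qBOLD signal model is extravascular).
    """
    if n_protons < 100:
        raise ValueError("need at least 100 protons")
    key = (
        radius, n_protons, seed, diffusion_coeff, dt, vf_ref, rs_factor,
        field, total_time, gamma,
    )
    if cache and key in _TABLE_CACHE:
        return _TABLE_CACHE[key]

    ck_times = np.arange(2.0, total_time + 1e-9, 2.0)
    ck_steps = np.round(ck_times / dt).astype(np.int64)
    if not np.allclose(ck_steps * dt, ck_times):
        raise ValueError("dt must divide the 2-ms checkpoint raster")
    n_steps = int(ck_steps[-1])

    rng = np.random.default_rng(seed)
    points, e1, e2, c_ext, w_in, n_cyl = _cylinder_mc.make_environments(
        n_protons, radius, vf_ref, rs_factor, gamma, field, rng
    )
    sigma = float(np.sqrt(2.0 * diffusion_coeff * dt))
    phases, inside0 = _cylinder_mc.walk_phases(
        seed + 1, n_steps, dt, sigma, radius**2,
        points, e1, e2, c_ext, w_in, n_cyl, ck_steps,
    )
    table = PhaseTable(
        radius=radius,
        times=ck_times,
        phases=np.ascontiguousarray(phases[~inside0]),
        vf_ref=vf_ref,
        total_time=total_time,
        n_protons=n_protons,
        seed=seed,
        diffusion_coeff=diffusion_coeff,
        dt=dt,
    )
    if cache:
        _TABLE_CACHE[key] = table
    return table


def _ase_phase_matrix(table: PhaseTable, taus: np.ndarray, te: float) -> np.ndarray:
    """Per-proton ASE echo phases, shape (n_tau, n_protons)."""
    cols = []
    phi_te = table.column(te)
    for tau in taus:
        phi_180 = table.column((te - tau) / 2.0)
        cols.append(2.0 * phi_180 - phi_te)
    return np.ascontiguousarray(np.stack(cols, axis=0))


def _ge_phase_matrix(table: PhaseTable, tes: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.stack([table.column(t) for t in tes], axis=0))


def _check_grid(grid: np.ndarray, step: float, kind: str) -> None:
    if np.any(np.abs(np.round(grid / step) * step - grid) > 1e-9):
        raise ValueError(f"{kind} grid points must be multiples of {step} ms")


def mc_single_radius(
    radius: float,
    saturation: float,
    hct: float,
    field: float = 3.0,
    kind: str = "ASE",
    grid: Sequence[float] | None = None,
    n_protons: int = 10_000,
    seed: int = 0,
    te: float = 80.0,
    diffusion_coeff: float = 1.0,
    dt: float = 0.1,
    vf_ref: float = 0.03,
    rs_factor: float = 30.0,
    dchi0: float = DCHI0,
    gamma: float = GAMMA,
) -> SignalCurve:
    """Monte Carlo attenuation curve for a single vessel radius.

    ``kind`` is ``"ASE"`` (tau grid, multiples of 4 ms, spin-echo refocusing
    displaced by tau) or ``"GE"`` (TE grid, multiples of 2 ms, no
    refocusing).  The returned attenuation corresponds to the reference
    volume fraction recorded in ``meta['vf_ref']``; rescale via
    :func:`mc_combine`.
    """
    if not 0 <= saturation <= 1:
        raise ValueError("saturation must lie in [0, 1]")
    if kind not in ("ASE", "GE"):
        raise ValueError("kind must be 'ASE' or 'GE'")
    if grid is None:
        grid = np.arange(0.0, 69.0, 4.0) if kind == "ASE" else np.arange(2.0, 81.0, 2.0)
    grid = np.asarray(grid, dtype=float)
    _check_grid(grid, 4.0 if kind == "ASE" else 2.0, kind)

    table = build_phase_table(
        radius, n_protons=n_protons, seed=seed, diffusion_coeff=diffusion_coeff,
        dt=dt, vf_ref=vf_ref, rs_factor=rs_factor, field=field,
        total_time=te, gamma=gamma,
    )
    dchi = dchi0 * hct * (1.0 - saturation)
    if kind == "ASE":
        phases = _ase_phase_matrix(table, grid, te)
    else:
        phases = _ge_phase_matrix(table, grid)
    att = _cylinder_mc.attenuation_from_phases(phases, dchi)
    meta = {
        "radius": radius, "saturation": saturation, "hct": hct, "field": field,
        "kind": kind, "vf_ref": vf_ref, "n_protons": n_protons, "seed": seed,
        "te": te, "diffusion_coeff": diffusion_coeff,
    }
    return SignalCurve(grid, att, meta)


def mc_combine(
    curves: Sequence[SignalCurve],
    volume_fractions: Sequence[float],
    target_times: Sequence[float],
) -> SignalCurve:
    """Combine per-radius curves into a tissue signal at requested times.

    Each curve's log-attenuation is rescaled from its simulated reference
    volume fraction to the compartment's volume fraction, the logs are
    summed (independent-compartment limit), and the total is linearly
    interpolated from the simulation raster to ``target_times``.
    """
    if len(curves) != len(volume_fractions):
        raise ValueError("one volume fraction per curve required")
    target = np.asarray(target_times, dtype=float)
    total = None
    grid = None
    for curve, vf in zip(curves, volume_fractions):
        if vf == 0:
            continue
        scale = vf / curve.meta.get("vf_ref", 1.0)
        ln_a = scale * np.log(curve.attenuation)
        if target.min() < curve.abscissa.min() or target.max() > curve.abscissa.max():
            raise ValueError("requested times extrapolate beyond the simulated grid")
        interp = np.interp(target, curve.abscissa, ln_a)
        total = interp if total is None else total + interp
        grid = curve.abscissa
    if total is None:  # all compartments empty
        total = np.zeros_like(target)
    return SignalCurve(target, np.exp(total), {"combined": True})


class MonteCarloForward:
    """Two-compartment (capillary + venous) Monte Carlo signal generator.

    Builds one phase table per vessel radius, then produces ASE tau-series
    and gradient-echo condition signals for arbitrary physiological states
    by exact susceptibility rescaling, at negligible per-state cost.  The
    capillary compartment (default radius 3 um) carries the capillary
    saturation and the volume CBVt - DBV; the venous compartment (default
    radius 30 um) carries the venous saturation and the volume DBV.
    """

    def __init__(
        self,
        n_protons: int = 10_000,
        seed: int = 0,
        diffusion_coeff: float = 1.0,
        dt: float = 0.1,
        vf_ref: float = 0.03,
        rs_factor: float = 30.0,
        capillary_radius: float = 3.0,
        venous_radius: float = 30.0,
        field: float = 3.0,
        ase_protocol: AseProtocol = AseProtocol(),
        bold_protocol: BoldProtocol = BoldProtocol(),
        constants: BloodGasConstants = BloodGasConstants(),
        dchi0: float = DCHI0,
        gamma: float = GAMMA,
    ) -> None:
        self.ase_protocol = ase_protocol
        self.bold_protocol = bold_protocol
        self.constants = constants
        self.field = field
        self.dchi0 = dchi0
        self.n_protons = n_protons

        te = ase_protocol.te
        if te % 2:
            raise ValueError("ASE TE must sit on the 2-ms simulation raster")
        taus = np.asarray(ase_protocol.taus, dtype=float)
        tau_max = 4.0 * np.ceil(taus.max() / 4.0)
        self._tau_grid = np.arange(0.0, tau_max + 1e-9, 4.0)
        bte = bold_protocol.te
        self._ge_grid = np.unique([2.0 * np.floor(bte / 2.0), 2.0 * np.ceil(bte / 2.0)])

        self._phase = {}
        for label, radius, sub in (
            ("capillary", capillary_radius, 0),
            ("venous", venous_radius, 1),
        ):
            table = build_phase_table(
                radius, n_protons=n_protons, seed=seed + sub,
                diffusion_coeff=diffusion_coeff, dt=dt, vf_ref=vf_ref,
                rs_factor=rs_factor, field=field, total_time=te, gamma=gamma,
            )
            self._phase[label] = {
                "ase": _ase_phase_matrix(table, self._tau_grid, te),
                "ge": _ge_phase_matrix(table, self._ge_grid),
                "vf_ref": table.vf_ref,
            }

    def _ln_attenuation(self, which: str, label: str, dchi: float, vf: float):
        comp = self._phase[label]
        att = _cylinder_mc.attenuation_from_phases(comp[which], dchi)
        return (vf / comp["vf_ref"]) * np.log(att)

    def ase_attenuation(self, state: PhysiologicalState, svo2: float, sco2: float):
        """ASE attenuation at the protocol taus for given compartment saturations."""
        ln_total = self._ln_attenuation(
            "ase", "capillary", self.dchi0 * state.hct * (1.0 - sco2),
            state.cbv_total - state.dbv,
        ) + self._ln_attenuation(
            "ase", "venous", self.dchi0 * state.hct * (1.0 - svo2), state.dbv
        )
        taus = np.asarray(self.ase_protocol.taus, dtype=float)
        return np.exp(np.interp(taus, self._tau_grid, ln_total))

    def bold_signal(self, state: PhysiologicalState, svo2: float, sco2: float):
        """Gradient-echo attenuation at the BOLD protocol TE."""
        ln_total = self._ln_attenuation(
            "ge", "capillary", self.dchi0 * state.hct * (1.0 - sco2),
            state.cbv_total - state.dbv,
        ) + self._ln_attenuation(
            "ge", "venous", self.dchi0 * state.hct * (1.0 - svo2), state.dbv
        )
        return float(np.exp(np.interp(self.bold_protocol.te, self._ge_grid, ln_total)))


def delta_bold_forward(
    state: PhysiologicalState,
    protocol: BoldProtocol = BoldProtocol(),
    model: str = "analytic",
    constants: BloodGasConstants = BloodGasConstants(),
    mc: MonteCarloForward | None = None,
    field: float = 3.0,
) -> float:
    """Percentage BOLD signal change between normoxia and hyperoxia.

    Simulates the gradient-echo signal with the normoxic venous/capillary
    saturations and again with the hyperoxic saturations (metabolic O2
    extraction held fixed), returning 100 (S_hyper - S_norm) / S_norm.
    Positive whenever OEF > 0 and the hyperoxic arterial pO2 exceeds the
    normoxic one.
    """
    norm, hyper = hyperoxia_pair(state, constants)
    if model == "analytic":
        te_s = protocol.te * 1e-3

        def ln_signal(oxy):
            u_v = characteristic_frequency(1.0 - oxy.svo2, state.hct, field) * te_s
            u_c = characteristic_frequency(1.0 - oxy.sco2, state.hct, field) * te_s
            return -(
                state.dbv * static_dephasing_fc(u_v)
                + (state.cbv_total - state.dbv) * static_dephasing_fc(u_c)
            )

        return 100.0 * float(np.expm1(ln_signal(hyper) - ln_signal(norm)))
    if model == "mc":
        if mc is None:
            mc = MonteCarloForward(bold_protocol=protocol, constants=constants,
                                   field=field)
        s_n = mc.bold_signal(state, norm.svo2, norm.sco2)
        s_h = mc.bold_signal(state, hyper.svo2, hyper.sco2)
        return 100.0 * (s_h - s_n) / s_n
    raise ValueError("model must be 'analytic' or 'mc'")
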