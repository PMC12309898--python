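"""Synthetic phantoms and physiological traces for end-to-end testing.

Generates aligned NIfTI phantom datasets with the statistical structure the
analysis pipeline assumes — an ASE tau-series, a hyperoxia-BOLD time series
with a petO2/petCO2 trace, and a TRUST tag/control series — together with
ground-truth parameter maps.  Phantoms contain a gray-matter (GM) shell
around a white-matter (WM) core on a 32 x 32 x 9 grid.

WM is given a *lower* venous blood volume than GM (vascular density) but a
*higher* effective R2' via an explicit R2' override, emulating the
non-heme (myelin) contribution to WM R2' that makes qBOLD OEF in WM
unphysiologically high; the GM/WM contrasts default to the ratios measured
in vivo (R2' GM/WM 0.78, venous DBV GM/WM 3.19).

Printed per-subject study tables are embedded as fixtures for the group
statistics.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import estimators
from .forward_models import (
    AseProtocol,
    BoldProtocol,
    TrustProtocol,
    delta_bold_forward,
    r2p_static_dephasing,
)
from .physiology import BloodGasConstants, PhysiologicalState

__all__ = [
    "PhantomSpec",
    "ParadigmSpec",
    "tissue_masks",
    "make_ase_phantom",
    "make_hyperoxia_phantom",
    "make_trust_phantom",
    "fixture_tables",
]

GM_WM_DBV_RATIO = 3.19
GM_WM_R2P_RATIO = 0.78


def _default_gm() -> PhysiologicalState:
    return PhysiologicalState()


def _default_wm() -> PhysiologicalState:
    gm = _default_gm()
    return replace(gm, dbv=gm.dbv / GM_WM_DBV_RATIO, cbv_total=0.03)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, per-tissue physiology and noise of the digital phantom.

    ``wm_r2p_override`` sets the effective WM R2' directly (s^-1),
    representing susceptibility sources other than deoxyhemoglobin; when
    None, WM R2' follows from its physiological state.  ``snr`` is the
    signal-to-noise ratio of the generated images (None: noiseless).
    """

    shape: tuple[int, int, int] = (32, 32, 9)
    gm: PhysiologicalState = field(default_factory=_default_gm)
    wm: PhysiologicalState = field(default_factory=_default_wm)
    wm_r2p_override: float | None = (
        r2p_static_dephasing(0.40, 0.34, 0.023) / GM_WM_R2P_RATIO
    )
    snr: float | None = None
    seed: int = 0


@dataclass(frozen=True)
class ParadigmSpec:
    """The 10-min hyperoxia respiratory paradigm.

    Three 2-min normoxia blocks interleaved with two 2-min hyperoxia blocks;
    petO2 moves between ``baseline_peto2`` and ``baseline_peto2 + delta_peto2``
    with first-order exponential transitions of time constant
    ``transition_tau`` seconds.  petCO2 stays near ``baseline_petco2``
    (isocapnia) up to a small jitter.
    """

    tr: float = 1.0
    n_volumes: int = 600
    block_length: float = 120.0
    baseline_peto2: float = 110.0
    delta_peto2: float = 300.0
    baseline_petco2: float = 39.0
    petco2_jitter: float = 0.2
    transition_tau: float = 10.0

    def block_edges(self) -> np.ndarray:
        total = self.n_volumes * self.tr
        edges = np.arange(0.0, total + 1e-9, self.block_length)
        if not np.isclose(edges[-1], total):
            raise ValueError("blocks must tile the acquisition")
        return edges

    def hyperoxic_profile(self, times: np.ndarray) -> np.ndarray:
        """Normalized 0..1 inspired-oxygen profile with exponential transitions."""
        edges = self.block_edges()
        target = np.zeros_like(times)
        for i in range(len(edges) - 1):
            level = 1.0 if i % 2 == 1 else 0.0
            target[(times >= edges[i]) & (times < edges[i + 1])] = level
        target[times >= edges[-1]] = 0.0
        out = np.empty_like(target)
        level = target[0]
        dt = np.diff(times, prepend=times[0])
        for i, (tg, d) in enumerate(zip(target, dt)):
            level += (tg - level) * (1.0 - np.exp(-d / self.transition_tau))
            out[i] = level
        return out


def tissue_masks(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint GM (shell) and WM (core) masks on the phantom grid."""
    nx, ny, nz = shape
    x, y = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), indexing="ij"
    )
    rho = np.sqrt(x**2 + y**2)[..., None] * np.ones((1, 1, nz))
    wm = rho < 0.35
    gm = (rho >= 0.35) & (rho < 0.75)
    return gm, wm


def _as_nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4))


def _tissue_params(spec: PhantomSpec):
    gm_r2p = r2p_static_dephasing(spec.gm.oef, spec.gm.hct, spec.gm.dbv)
    wm_r2p = (
        spec.wm_r2p_override
        if spec.wm_r2p_override is not None
        else r2p_static_dephasing(spec.wm.oef, spec.wm.hct, spec.wm.dbv)
    )
    return (spec.gm, gm_r2p), (spec.wm, wm_r2p)


def make_ase_phantom(
    spec: PhantomSpec = PhantomSpec(),
    protocol: AseProtocol = AseProtocol(),
    out_dir: str | Path | None = None,
):
    """Generate the 4-D ASE tau-series phantom and its truth maps.

    Per-voxel signals follow the analytic two-regime static-dephasing model
    with the tissue's (R2', DBV); optional Gaussian noise at ``spec.snr``.
    Returns ``(img4d, truth, masks)`` where ``truth`` maps names
    (``r2p``, ``dbv``, ``oef``) to NIfTI images (OEF from the R2'/DBV
    quotient, unclipped — the WM override makes it unphysiological on
    purpose) and ``masks`` holds the GM/WM masks.  If ``out_dir`` is given,
    everything is written there along with a JSON sidecar.
    """
    gm_mask, wm_mask = tissue_masks(spec.shape)
    taus = np.asarray(protocol.taus, dtype=float)
    data = np.zeros(spec.shape + (taus.size,))
    r2p_map = np.zeros(spec.shape)
    dbv_map = np.zeros(spec.shape)
    s0 = 100.0

    for (state, r2p), mask in zip(_tissue_params(spec), (gm_mask, wm_mask)):
        curve = _two_regime_signal(taus, r2p, state.dbv, np.log(s0))
        data[mask] = curve
        r2p_map[mask] = r2p
        dbv_map[mask] = state.dbv

    rng = np.random.default_rng(spec.seed)
    if spec.snr is not None:
        data = data + rng.normal(0.0, s0 / spec.snr, size=data.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        oef_map = estimators.oef_from_r2p_dbv(r2p_map, dbv_map)
    img = _as_nifti(data)
    truth = {"r2p": _as_nifti(r2p_map), "dbv": _as_nifti(dbv_map),
             "oef": _as_nifti(oef_map)}
    masks = {"gm": _as_nifti(gm_mask.astype(float)),
             "wm": _as_nifti(wm_mask.astype(float))}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nib.save(img, out / "ase.nii")
        for name, m in {**truth, **masks}.items():
            nib.save(m, out / f"truth_{name}.nii")
        (out / "ase.json").write_text(json.dumps(
            {"taus_ms": list(taus), "te_ms": protocol.te, "seed": spec.seed}
        ))
    return img, truth, masks


def _two_regime_signal(taus, r2p, dbv, ln_s0, tau_transition=15.0):
    tau_s = taus * 1e-3
    ln_s = np.full_like(tau_s, ln_s0)
    long_mask = taus > tau_transition
    ln_s[long_mask] += dbv - r2p * tau_s[long_mask]
    short = (taus > 0) & ~long_mask
    if dbv > 0:
        dw = r2p / dbv
        ln_s[short] -= 0.3 * dbv * (dw * tau_s[short]) ** 2
    return np.exp(ln_s)


def make_hyperoxia_phantom(
    spec: PhantomSpec = PhantomSpec(),
    paradigm: ParadigmSpec = ParadigmSpec(),
    protocol: BoldProtocol = BoldProtocol(),
    constants: BloodGasConstants = BloodGasConstants(),
    out_dir: str | Path | None = None,
):
    """Generate the hyperoxia-BOLD phantom, its petO2/petCO2 trace and truths.

    Each tissue's fractional BOLD response (deltaBOLD) is computed from its
    physiological state with the analytic forward model and applied along
    the normalized hyperoxic profile; the petO2 trace shares that profile.
    Returns ``(img4d, trace, truth)`` where ``trace`` is a DataFrame with
    columns time/peto2/petco2 and ``truth`` holds per-voxel deltaBOLD (%)
    and DBV maps.
    """
    gm_mask, wm_mask = tissue_masks(spec.shape)
    times = np.arange(protocol.n_volumes) * protocol.tr
    profile = paradigm.hyperoxic_profile(times)

    rng = np.random.default_rng(spec.seed + 1)
    peto2 = paradigm.baseline_peto2 + paradigm.delta_peto2 * profile
    petco2 = paradigm.baseline_petco2 + rng.normal(
        0.0, paradigm.petco2_jitter, size=times.size
    )
    trace = pd.DataFrame({"time": times, "peto2": peto2, "petco2": petco2})

    s0 = 100.0
    data = np.zeros(spec.shape + (times.size,))
    dbold_map = np.zeros(spec.shape)
    dbv_map = np.zeros(spec.shape)
    for (state, _), mask in zip(_tissue_params(spec), (gm_mask, wm_mask)):
        pstate = replace(
            state,
            pao2_norm=paradigm.baseline_peto2,
            pao2_hyper=paradigm.baseline_peto2 + paradigm.delta_peto2,
        )
        dbold = delta_bold_forward(pstate, protocol, "analytic", constants)
        data[mask] = s0 * (1.0 + dbold / 100.0 * profile)
        dbold_map[mask] = dbold
        dbv_map[mask] = state.dbv
    if spec.snr is not None:
        data = data + rng.normal(0.0, s0 / spec.snr, size=data.shape)

    img = _as_nifti(data)
    truth = {"delta_bold": _as_nifti(dbold_map), "dbv": _as_nifti(dbv_map)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nib.save(img, out / "bold.nii")
        trace.to_csv(out / "physio.tsv", sep="\t", index=False)
        for name, m in truth.items():
            nib.save(m, out / f"truth_{name}.nii")
        (out / "bold.json").write_text(json.dumps(
            {"tr_s": protocol.tr, "te_ms": protocol.te, "seed": spec.seed}
        ))
    return img, trace, truth


def make_trust_phantom(
    svo2_true: float = 0.60,
    protocol: TrustProtocol = TrustProtocol(),
    shape: tuple[int, int, int] = (32, 32, 9),
    hct: float = 0.42,
    t1b: float = 1624.0,
    snr: float | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Generate a TRUST tag/control series with a sagittal-sinus blob.

    The blood (control - tag) difference in the blob decays over eTE with
    the blood T2 implied by ``svo2_true`` through the calibration model at
    the large-vessel hematocrit; the background is static tissue.  Returns
    ``(img4d, truth)`` with the generating SvO2, OEF, T2b and exponent.
    """
    if not 0 < svo2_true < 1:
        raise ValueError("svo2_true must lie in (0, 1)")
    calib = estimators.CalibrationModel.for_hct(hct)
    t2b = calib.t2b(svo2_true)
    c = 1.0 / t1b - 1.0 / t2b  # ms^-1, negative for decay
    etes = np.asarray(protocol.etes, dtype=float)

    background, blood = 50.0, 40.0
    blob = np.zeros(shape, dtype=bool)
    cx, cy = shape[0] // 2, int(shape[1] * 0.85)
    blob[cx - 1 : cx + 1, cy - 1 : cy + 1, shape[2] // 2] = True

    n_vol = len(etes) * protocol.n_repeats * 2
    data = np.full(shape + (n_vol,), background)
    v = 0
    for ete in etes:
        ds = blood * np.exp(ete * c)
        for _ in range(protocol.n_repeats):
            control = np.where(blob, background + ds, background)
            tag = np.full(shape, background)
            data[..., v] = control  # control first, then tag
            data[..., v + 1] = tag
            v += 2
    if snr is not None:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, background / snr, size=data.shape)
    img = _as_nifti(data)
    truth = {"svo2": svo2_true, "oef": 1.0 - svo2_true, "t2b": t2b,
             "c_exponent": c, "blob": blob}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nib.save(img, out / "trust.nii")
        (out / "trust.json").write_text(json.dumps(
            {"etes_ms": list(etes), "n_repeats": protocol.n_repeats,
             "svo2_true": svo2_true, "seed": seed}
        ))
    return img, truth


_TABLE_GAS = """\
subject peto2 delta_peto2 petco2 delta_petco2
1 122.9 321.5 34.9 1.0
2 108.9 277.8 41.7 1.2
3 109.8 295.6 43.3 0.5
4 109.2 297.0 41.3 -0.2
5 104.9 291.0 39.6 -0.1
6 109.3 268.2 39.5 2.3
7 112.0 296.9 36.3 -0.5
8 128.8 312.6 35.4 0.5
9 128.8 277.7 37.0 0.6
10 109.0 308.7 42.2 -1.1
"""

_TABLE_REGIONAL = """\
subject r2p_sq r2p_sq_iqr dbv_sq dbv_sq_iqr oef_sq oef_sq_iqr r2p_hq r2p_hq_iqr dbv_hq dbv_hq_iqr oef_hq oef_hq_iqr oef_trust
1 2.1 1.9 2.9 5.0 15.6 25.9 2.1 1.9 1.2 1.9 40.7 88.1 38.6
2 2.1 1.5 1.9 4.4 15.1 38.2 2.1 1.5 2.5 1.9 25.0 26.1 34.5
3 2.8 2.3 3.8 8.7 12.6 22.5 2.8 2.3 1.4 1.6 50.5 77.3 34.2
4 3.1 1.7 4.0 3.5 22.5 17.5 3.1 1.7 1.5 1.5 55.7 60.6 41.5
5 1.9 2.0 3.0 5.4 13.5 21.9 1.9 2.0 1.5 1.5 34.3 50.7 27.4
6 2.6 1.8 4.3 4.7 16.5 18.1 2.6 1.8 2.6 2.0 30.2 31.2 36.5
7 2.7 1.9 4.0 4.8 17.2 18.9 2.7 1.9 1.2 1.2 63.4 79.3 53.7
8 3.1 2.4 4.5 5.0 19.7 20.9 3.1 2.4 1.5 1.7 53.1 76.7 44.7
9 2.6 2.9 3.5 7.4 13.5 26.0 2.6 2.9 1.1 1.7 45.2 98.6 49.0
10 4.1 3.8 6.9 10.3 15.0 12.7 4.1 3.8 1.6 2.0 58.6 111.7 45.6
"""

_TABLE_RATIOS = """\
subject r2p_ratio dbv_sq_ratio dbv_hq_ratio
1 0.64 0.60 2.76
2 0.77 0.48 3.01
3 0.80 0.74 3.07
4 0.76 0.70 2.63
5 0.71 0.74 2.99
6 0.84 0.89 2.82
7 0.86 0.80 3.61
8 0.76 0.68 3.92
9 0.90 0.74 3.04
10 0.74 0.72 4.10
"""


def fixture_tables() -> dict[str, pd.DataFrame]:
    """Per-subject study fixtures for regression tests of group statistics.

    Returns three DataFrames: ``gas`` (baseline petO2/petCO2 and their
    hyperoxia-induced changes, mmHg), ``regional`` (global-GM medians with
    IQRs of R2' s^-1, DBV %, OEF % per method plus TRUST OEF %), and
    ``ratios`` (GM/WM ratios of R2' and of DBV per method).  Group means
    and SDs are always recomputed from these rows, never stored.
    """
    return {
        name: pd.read_csv(io.StringIO(text), sep=r"\s+")
        for name, text in (
            ("gas", _TABLE_GAS),
            ("regional", _TABLE_REGIONAL),
            ("ratios", _TABLE_RATIOS),
        )
    }
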