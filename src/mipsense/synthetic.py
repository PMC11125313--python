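"""Synthetic plate images and batch-adsorption datasets.

Emulates the experimental designs the analysis modules expect: calibration
plates exposed to 0-20 mg/L tartrazine (3 mL aliquot, 1 cm^2 plate, complete
uptake), uptake-vs-time curves following the pseudo-first-order,
pseudo-second-order or intraparticle-diffusion closed forms, equilibrium
isotherms following Langmuir or Freundlich, and MIP/NIP selectivity batches
with prescribed removal percentages.

The plate color response is a decadic-exponential (Beer-Lambert-like in
reflectance) attenuation of each RGB channel with surface loading
q = C*V/A (mg/cm^2): ch(q) = base_ch * 10**(-att_ch * q). The blue channel
attenuates fastest, green next, red least, so loaded plates turn yellow.
This response law is a modelling convention of this package, not a measured
camera characterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateResponseModel",
    "BatchDesign",
    "generate_plate_image",
    "generate_calibration_series",
    "generate_kinetics",
    "generate_isotherm",
    "generate_selectivity_experiment",
]

_KINETIC_MODELS = {"PFO", "PSO", "IPD"}
_ISOTHERM_MODELS = {"Langmuir", "Freundlich"}
_REQUIRED_PARAMS = {
    "PFO": ("Qe", "k1"),
    "PSO": ("Qe", "k2"),
    "IPD": ("kid", "C"),
    "Langmuir": ("Qm", "b"),
    "Freundlich": ("Kf", "n"),
}


@dataclass(frozen=True)
class PlateResponseModel:
    """Color response of a MIP-PET plate to tartrazine surface loading.

    Attenuation coefficients are decadic, per (mg/cm^2) of loading. The
    ordering blue > green >= red >= 0 makes loaded plates yellow.

    Parameters
    ----------
    base_rgb : tuple of float
        Channel means of a blank plate on the 8-bit scale.
    red_attenuation, green_attenuation, blue_attenuation : float
        Decadic attenuation per unit loading for each channel.
    pixel_noise_sd : float
        Per-pixel, per-channel Gaussian noise SD in 8-bit counts.
    illumination_gradient : float
        Maximum fractional brightness change across the plate; realized as a
        linear left-to-right field centered on 1, so the plate mean is
        unaffected.
    saturation_loading : float
        Plate adsorption capacity per area (mg/cm^2). The effective loading
        that colors the plate is q_max * tanh(q / q_max): linear at low
        loading, saturating once the nominal loading approaches the plate's
        capacity, where the complete-uptake assumption breaks down. Use
        ``inf`` for an ideal (capacity-free) response.
    seed : int
        Master RNG seed for every stochastic element.
    """

    base_rgb: tuple[float, float, float] = (235.0, 230.0, 225.0)
    red_attenuation: float = 0.5
    green_attenuation: float = 1.2
    blue_attenuation: float = 10.0
    pixel_noise_sd: float = 2.0
    illumination_gradient: float = 0.02
    saturation_loading: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.red_attenuation <= self.green_attenuation < self.blue_attenuation):
            raise ValueError(
                "attenuation coefficients must satisfy "
                "blue > green >= red >= 0; got "
                f"red={self.red_attenuation}, green={self.green_attenuation}, "
                f"blue={self.blue_attenuation}"
            )
        if self.pixel_noise_sd < 0:
            raise ValueError(f"pixel_noise_sd must be >= 0, got {self.pixel_noise_sd}")
        if any(not 0 <= ch <= 255 for ch in self.base_rgb):
            raise ValueError(f"base_rgb channels must lie in [0, 255], got {self.base_rgb}")
        if self.saturation_loading <= 0:
            raise ValueError(
                f"saturation_loading must be > 0 (use inf to disable), "
                f"got {self.saturation_loading}"
            )

    @property
    def attenuations(self) -> np.ndarray:
        return np.array(
            [self.red_attenuation, self.green_attenuation, self.blue_attenuation]
        )


@dataclass(frozen=True)
class BatchDesign:
    """Design of one synthetic batch-adsorption experiment.

    ``model_name`` selects the generating closed form; ``model_params`` holds
    its named constants (PFO: Qe, k1; PSO: Qe, k2; IPD: kid, C;
    Langmuir: Qm, b; Freundlich: Kf, n). ``noise_sd`` is the relative SD of
    multiplicative Gaussian noise applied to Q.
    """

    Co_list: tuple[float, ...] = (10.0,)
    V: float = 0.010
    A: float = 1.0
    times: tuple[float, ...] = tuple(float(t) for t in range(10, 130, 10))
    model_name: str = "PFO"
    model_params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_name not in _KINETIC_MODELS | _ISOTHERM_MODELS:
            raise ValueError(
                f"unknown model {self.model_name!r}; expected one of "
                f"{sorted(_KINETIC_MODELS | _ISOTHERM_MODELS)}"
            )
        if any(c < 0 for c in self.Co_list):
            raise ValueError("initial concentrations must be >= 0")
        if self.V < 0 or self.A < 0:
            raise ValueError("volume and area must be >= 0")
        if any(t < 0 for t in self.times):
            raise ValueError("times must be >= 0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    def require_params(self) -> dict:
        missing = [p for p in _REQUIRED_PARAMS[self.model_name] if p not in self.model_params]
        if missing:
            raise ValueError(
                f"model {self.model_name!r} requires parameters {missing}"
            )
        params = {k: float(self.model_params[k]) for k in _REQUIRED_PARAMS[self.model_name]}
        # C may legitimately be zero (boundary-layer intercept); rates must not be negative
        for k, v in params.items():
            if v < 0:
                raise ValueError(f"parameter {k} must be >= 0, got {v}")
        return params


def _illumination_field(width: int, height: int, gradient: float) -> np.ndarray:
    """Linear left-to-right brightness field centered on 1."""
    if width == 1:
        col = np.zeros(1)
    else:
        col = np.linspace(-0.5, 0.5, width)
    return np.broadcast_to(1.0 + gradient * col, (height, width)).copy()


def expected_channel_means(
    conc_mg_per_L: float,
    volume_L: float,
    area_cm2: float,
    response: PlateResponseModel,
) -> np.ndarray:
    """Noise-free expected (R, G, B) means for a plate, before clipping."""
    loading = conc_mg_per_L * volume_L / area_cm2
    q_max = response.saturation_loading
    if np.isfinite(q_max):
        loading = q_max * np.tanh(loading / q_max)
    base = np.asarray(response.base_rgb, dtype=float)
    return base * 10.0 ** (-response.attenuations * loading)


def generate_plate_image(
    conc_mg_per_L: float,
    volume_L: float,
    area_cm2: float,
    response: PlateResponseModel,
    width_px: int = 64,
    height_px: int = 64,
) -> np.ndarray:
    """Render one plate as an (H, W, 3) uint8 array.

    The whole aliquot is assumed adsorbed, so the surface loading is
    q = conc * volume / area. Each channel is attenuated decadically,
    modulated by the illumination field, perturbed by i.i.d. Gaussian pixel
    noise, then clipped to [0, 255] and rounded. Identical inputs (including
    the response seed) give a bit-identical image.
    """
    if conc_mg_per_L < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_mg_per_L}")
    if width_px < 16 or height_px < 16:
        raise ValueError(
            f"image must be at least 16x16 px, got {width_px}x{height_px}"
        )
    if volume_L < 0 or area_cm2 <= 0:
        raise ValueError("volume must be >= 0 and area > 0")

    means = expected_channel_means(conc_mg_per_L, volume_L, area_cm2, response)
    illum = _illumination_field(width_px, height_px, response.illumination_gradient)
    img = means[None, None, :] * illum[:, :, None]
    if response.pixel_noise_sd > 0:
        rng = np.random.default_rng(response.seed)
        img = img + rng.normal(0.0, response.pixel_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_calibration_series(
    concs: list[float],
    response: PlateResponseModel,
    replicates: int = 2,
    volume_L: float = 0.003,
    area_cm2: float = 1.0,
    width_px: int = 64,
    height_px: int = 64,
) -> list[tuple[np.ndarray, float]]:
    """Labelled plate images for a calibration series.

    Defaults mirror the calibration design: a 3 mL aliquot on a 1 cm^2 plate.
    Per-image seeds are derived deterministically from the response seed and
    the sample index, so the whole series is reproducible.
    """
    if len(concs) == 0:
        raise ValueError("concs must be non-empty")
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be >= 0")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")

    seeds = np.random.SeedSequence(response.seed).generate_state(
        len(concs) * replicates
    ) % (2**31)
    out: list[tuple[np.ndarray, float]] = []
    idx = 0
    for conc in concs:
        for _ in range(replicates):
            resp_i = PlateResponseModel(
                base_rgb=response.base_rgb,
                red_attenuation=response.red_attenuation,
                green_attenuation=response.green_attenuation,
                blue_attenuation=response.blue_attenuation,
                pixel_noise_sd=response.pixel_noise_sd,
                illumination_gradient=response.illumination_gradient,
                saturation_loading=response.saturation_loading,
                seed=int(seeds[idx]),
            )
            out.append(
                (
                    generate_plate_image(
                        conc, volume_L, area_cm2, resp_i, width_px, height_px
                    ),
                    float(conc),
                )
            )
            idx += 1
    return out


def pfo_curve(t: np.ndarray, Qe: float, k1: float) -> np.ndarray:
    """Pseudo-first-order uptake: Qt = Qe * (1 - exp(-k1 t))."""
    return Qe * (1.0 - np.exp(-k1 * np.asarray(t, dtype=float)))


def pso_curve(t: np.ndarray, Qe: float, k2: float) -> np.ndarray:
    """Pseudo-second-order uptake: Qt = k2 Qe^2 t / (1 + k2 Qe t)."""
    t = np.asarray(t, dtype=float)
    return k2 * Qe**2 * t / (1.0 + k2 * Qe * t)


def ipd_curve(t: np.ndarray, kid: float, C: float) -> np.ndarray:
    """Intraparticle diffusion: Qt = kid * sqrt(t) + C."""
    return kid * np.sqrt(np.asarray(t, dtype=float)) + C


def langmuir_curve(Ce: np.ndarray, Qm: float, b: float) -> np.ndarray:
    """Langmuir isotherm: Qe = Qm b Ce / (1 + b Ce)."""
    Ce = np.asarray(Ce, dtype=float)
    return Qm * b * Ce / (1.0 + b * Ce)


def freundlich_curve(Ce: np.ndarray, Kf: float, n: float) -> np.ndarray:
    """Freundlich isotherm: Qe = Kf * Ce^(1/n)."""
    return Kf * np.asarray(Ce, dtype=float) ** (1.0 / n)


def generate_kinetics(design: BatchDesign) -> pd.DataFrame:
    """Uptake-vs-time table (columns ``t_min``, ``Qt_mg_per_cm2``)."""
    if design.model_name not in _KINETIC_MODELS:
        raise ValueError(
            f"kinetic generation needs model in {sorted(_KINETIC_MODELS)}, "
            f"got {design.model_name!r}"
        )
    p = design.require_params()
    t = np.asarray(design.times, dtype=float)
    if design.model_name == "PFO":
        qt = pfo_curve(t, p["Qe"], p["k1"])
    elif design.model_name == "PSO":
        qt = pso_curve(t, p["Qe"], p["k2"])
    else:
        qt = ipd_curve(t, p["kid"], p["C"])
    if design.noise_sd > 0:
        rng = np.random.default_rng(design.seed)
        qt = qt * (1.0 + rng.normal(0.0, design.noise_sd, size=qt.shape))
    return pd.DataFrame({"t_min": t, "Qt_mg_per_cm2": qt})


def generate_isotherm(design: BatchDesign) -> pd.DataFrame:
    """Equilibrium isotherm table (columns ``Ce_mg_per_L``, ``Qe_mg_per_cm2``).

    The design's initial concentrations are used directly as the equilibrium
    concentrations of the generating closed form.
    """
    if design.model_name not in _ISOTHERM_MODELS:
        raise ValueError(
            f"isotherm generation needs model in {sorted(_ISOTHERM_MODELS)}, "
            f"got {design.model_name!r}"
        )
    p = design.require_params()
    for k, v in p.items():
        if v <= 0:
            raise ValueError(f"isotherm parameter {k} must be > 0, got {v}")
    ce = np.asarray(design.Co_list, dtype=float)
    if design.model_name == "Langmuir":
        qe = langmuir_curve(ce, p["Qm"], p["b"])
    else:
        qe = freundlich_curve(ce, p["Kf"], p["n"])
    if design.noise_sd > 0:
        rng = np.random.default_rng(design.seed)
        qe = qe * (1.0 + rng.normal(0.0, design.noise_sd, size=qe.shape))
    return pd.DataFrame({"Ce_mg_per_L": ce, "Qe_mg_per_cm2": qe})


def generate_selectivity_experiment(
    removal_mip: dict[str, float],
    removal_nip: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    Co: float = 100.0,
    V: float = 0.010,
    A: float = 1.0,
) -> pd.DataFrame:
    """Batch records realizing prescribed MIP and NIP removal percentages.

    Emits one row per (dye, sorbent) with Ce = Co * (1 - removal/100) plus
    optional relative Gaussian noise on Ce. Columns follow the batch CSV
    schema: ``label, sorbent, Co, Ce, V_L, A_cm2``.
    """
    if set(removal_mip) != set(removal_nip):
        raise ValueError(
            "MIP and NIP removal maps must share dye keys; "
            f"got {sorted(removal_mip)} vs {sorted(removal_nip)}"
        )
    for m in (removal_mip, removal_nip):
        for dye, r in m.items():
            if not 0 <= r <= 100:
                raise ValueError(f"removal for {dye!r} must lie in [0, 100], got {r}")
    rng = np.random.default_rng(seed)
    rows = []
    for dye in removal_mip:
        for sorbent, removal in (("MIP", removal_mip[dye]), ("NIP", removal_nip[dye])):
            ce = Co * (1.0 - removal / 100.0)
            if noise_sd > 0:
                ce = max(0.0, ce * (1.0 + rng.normal(0.0, noise_sd)))
            rows.append(
                {"label": dye, "sorbent": sorbent, "Co": Co, "Ce": ce, "V_L": V, "A_cm2": A}
            )
    return pd.DataFrame(rows)
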