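"""Synthetic spectro-kinetic data with full ground truth.

Generates every input the analysis pipeline consumes: multi-window
transient-absorption matrices from a branched photocycle scheme and a
Gaussian-band spectral library, stepwise photoconversion series, and binding
titrations.  Defaults reproduce the conditions of the CarH photoreceptor
study this package models: the branched photocycle with its published rate
constants, cobalamin-like band positions, a ~170 fs Gaussian IRF for the
ultrafast window, an inverted flat pre-t0 baseline from the >1 ms
intermediate, and homoscedastic Gaussian noise.  Every generator is
deterministic under a fixed seed and returns a ground-truth record sufficient
to score recovery without external information.

Absolute amplitude scales of the intermediate spectra are not published, so
transient matrices are normalized to unit peak |ΔA|; a ``noise_rms`` in OD is
then also the relative noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .globalfit import exp_conv_gauss, gauss_step
from .io import SpectroTemporalMatrix, ValidationError
from .binding import BindingSeries, binding_fraction
from .target import KineticScheme, _eigen_terms

# ---------------------------------------------------------------------------
# published photocycle rate constants (s^-1)

RATES = {
    "k_D": 0.471e12,        # direct excited-state relaxation to the ground state
    "k_HomoC": 0.012e12,    # Co–C homolysis -> cob(II)alamin radical pair
    "k_CT": 0.044e12,       # charge transfer -> MLCT intermediate (productive)
    "k_RPR": 1.26e9,        # radical-pair recombination
    "k_HeteroC": 0.1e9,     # heterolysis, MLCT -> five-coordinate cob(III)alamin
    "k_R": 1.79e6,          # structural rearrangement
    "k_AF": 0.1e3,          # adduct formation
    "k_Diss": 1.71,         # first tetramer-dissociation step
    "k_DissP": 0.06,        # second (slower) dissociation step
}

#: total depopulation rate of the initial excited state
K1 = RATES["k_D"] + RATES["k_HomoC"] + RATES["k_CT"]

#: decay lifetime of the photoproduct (light-state) excited state, s
LS_EXCITED_LIFETIME = 3.2e-12

# ---------------------------------------------------------------------------
# Gaussian-band spectral library: (center nm, FWHM nm, amplitude OD)

BAND_PRESETS = {
    # dark-state chromophore: visible double peak plus the UV gamma band
    "carh_gs": [(360, 34, 0.75), (510, 28, 0.95), (540, 26, 0.90)],
    # light-state adduct: structured visible peaks and split UV features
    "carh_ls": [(333, 22, 0.80), (358, 22, 0.85), (478, 20, 0.85),
                (509, 20, 0.95)],
    # initial excited state: broad absorption flanking the bleached region
    "gs_excited": [(440, 55, 0.75), (615, 65, 0.55)],
    # cob(II)alamin radical
    "cob2alamin": [(315, 40, 0.55), (470, 50, 0.75)],
    # metal-to-ligand charge-transfer intermediate
    "mlct": [(380, 30, 0.55), (455, 35, 0.80), (590, 45, 0.55)],
    # five-coordinate cob(III)alamin after heterolysis
    "cob3_heterolysis": [(350, 30, 0.72), (480, 42, 0.62), (545, 36, 0.45)],
    # same chromophore after rearrangement: blue shift, UV growth
    "cob3_shifted": [(352, 30, 0.85), (468, 40, 0.62), (528, 34, 0.42)],
    # protein-cobalamin adduct before/during tetramer dissociation
    "adduct_early": [(333, 22, 0.55), (358, 22, 0.62), (478, 20, 0.80),
                     (509, 20, 0.90)],
    "adduct_late": [(333, 22, 0.70), (358, 22, 0.76), (478, 20, 0.83),
                    (509, 20, 0.93)],
    # light-state excited state (charge-transfer-like, broad)
    "ls_excited": [(365, 42, 0.70), (545, 58, 0.50)],
    # free cobalamin in solution (titration ligand)
    "free_cbl": [(375, 32, 0.70), (525, 42, 0.85)],
}

DEFAULT_SPECIES_BANDS = {
    "GS": "carh_gs", "A": "gs_excited", "B": "cob2alamin", "C": "mlct",
    "Dstar": "cob3_heterolysis", "D": "cob3_shifted", "Estar": "adduct_early",
    "E": "adduct_late", "LS": "carh_ls", "LSstar": "ls_excited",
}


def default_wavelengths() -> np.ndarray:
    """300–700 nm in 5 nm steps (81 points)."""
    return np.arange(300.0, 700.0 + 1e-9, 5.0)


def band_spectrum(bands, wavelengths) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    out = np.zeros_like(wl)
    for center, fwhm, amp in bands:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out += amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return out


def species_spectrum(label: str, wavelengths,
                     bands_map=None) -> np.ndarray:
    bands_map = bands_map or DEFAULT_SPECIES_BANDS
    return band_spectrum(BAND_PRESETS[bands_map[label]], wavelengths)


# ---------------------------------------------------------------------------
# photocycle schemes

def full_photocycle() -> KineticScheme:
    """The complete branched photocycle with the published rates."""
    return KineticScheme(
        species=["GS", "A", "B", "C", "Dstar", "D", "Estar", "E", "LS"],
        edges=[
            ("A", "GS", RATES["k_D"]),
            ("A", "B", RATES["k_HomoC"]),
            ("A", "C", RATES["k_CT"]),
            ("B", "GS", RATES["k_RPR"]),
            ("C", "Dstar", RATES["k_HeteroC"]),
            ("Dstar", "D", RATES["k_R"]),
            ("D", "Estar", RATES["k_AF"]),
            ("Estar", "E", RATES["k_Diss"]),
            ("E", "LS", RATES["k_DissP"]),
        ],
        excited_entry="A",
        ground_state="GS",
    )


def fs_ns_scheme() -> KineticScheme:
    """Ultrafast sub-scheme.

    Everything slower than the 3 ns window is terminal: the MLCT intermediate
    appears static within the window (heterolysis at ~0.1/ns happens beyond
    it) and is carried by the non-decaying component of the fit.
    """
    return KineticScheme(
        species=["GS", "A", "B", "C"],
        edges=[
            ("A", "GS", RATES["k_D"]),
            ("A", "B", RATES["k_HomoC"]),
            ("A", "C", RATES["k_CT"]),
            ("B", "GS", RATES["k_RPR"]),
        ],
        excited_entry="A",
        ground_state="GS",
    )


def ns_us_scheme() -> KineticScheme:
    """Streak-window sub-scheme: rearrangement into the >1 ms intermediate."""
    return KineticScheme(
        species=["Dstar", "D"],
        edges=[("Dstar", "D", RATES["k_R"])],
        excited_entry="Dstar",
    )


def ms_s_scheme() -> KineticScheme:
    """Slow sub-scheme: the two dissociation steps into the light state."""
    return KineticScheme(
        species=["Estar", "E", "LS"],
        edges=[("Estar", "E", RATES["k_Diss"]), ("E", "LS", RATES["k_DissP"])],
        excited_entry="Estar",
    )


def ls_photoresponse_scheme() -> KineticScheme:
    """Photoproduct excited state decaying straight back to its ground state."""
    return KineticScheme(
        species=["LS", "LSstar"],
        edges=[("LSstar", "LS", 1.0 / LS_EXCITED_LIFETIME)],
        excited_entry="LSstar",
        ground_state="LS",
    )


WINDOW_SCHEMES = {"fs_ns": fs_ns_scheme, "ns_us": ns_us_scheme,
                  "ms_s": ms_s_scheme}


def default_time_axis(window: str) -> np.ndarray:
    if window == "fs_ns":
        # 20 linear pre-t0 points plus 100 log-spaced delays, emulating
        # randomized delay acquisition between -1.5 ps and 3 ns
        return np.concatenate([np.linspace(-1.5e-12, -2e-13, 20),
                               np.geomspace(1e-13, 3e-9, 100)])
    if window == "ns_us":
        return np.geomspace(2e-9, 5e-6, 150)
    if window == "ms_s":
        # 12.5 ms sampling, 4,800 points
        return 12.5e-3 * np.arange(1, 4801)
    raise ValidationError(f"no default time axis for window {window!r}")


@dataclass
class SyntheticSpec:
    """Everything needed to generate one transient matrix deterministically."""

    scheme: KineticScheme | None = None          # default: per-window sub-scheme
    bands: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_BANDS))
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    irf_fwhm: float = 170e-15                    # applied to fs_ns only
    noise_rms: float = 0.005                     # OD, after unit-peak scaling
    excited_fraction: float = 0.10
    seed: int = 0
    include_pre_t0_offset: bool = True
    pre_t0_amplitude: float = 0.05               # peak |offset| in OD
    gs_label: str = "GS"                         # reference (bleached) species
    offset_label: str = "D"                      # the >1 ms species


def _convolved_concentrations(scheme: KineticScheme, times, irf_fwhm):
    """IRF-convolved concentrations of the observed species.

    Linear in the eigen-modes, so each exp / step term is replaced by its
    Gaussian-convolved closed form.
    """
    A, lam = _eigen_terms(scheme)
    t = np.asarray(times, dtype=float)
    scale = max(np.abs(lam).max(), 1.0)
    cols = np.zeros((t.size, len(scheme.species)))
    for m, lm in enumerate(lam):
        rate = -lm
        if rate <= 1e-12 * scale:
            f = gauss_step(t, 0.0, irf_fwhm)
        else:
            f = exp_conv_gauss(t, 1.0 / rate, 0.0, irf_fwhm)
        cols += np.outer(f, A[:, m])
    rows = [scheme.species.index(s) for s in scheme.observed_species]
    return cols[:, rows]


def generate_transient(spec: SyntheticSpec, window: str):
    """Synthetic ΔA matrix for one time window plus its ground truth.

    ΔA = excited_fraction · C(scheme) · (S_species − S_GS), IRF-convolved for
    the ultrafast window, normalized to unit peak |ΔA|, plus the flat inverted
    pre-t0 baseline of the >1 ms intermediate (fs_ns only, if enabled) and
    seeded Gaussian noise.
    """
    if window not in WINDOW_SCHEMES:
        raise ValidationError(f"unknown window {window!r}")
    scheme = spec.scheme if spec.scheme is not None else WINDOW_SCHEMES[window]()
    times = default_time_axis(window)
    irf = spec.irf_fwhm if window == "fs_ns" else 0.0
    wl = np.asarray(spec.wavelengths, dtype=float)

    gs = band_spectrum(BAND_PRESETS[spec.bands[spec.gs_label]], wl)
    observed = scheme.observed_species
    d_spectra = np.array([
        band_spectrum(BAND_PRESETS[spec.bands[s]], wl) - gs for s in observed
    ])
    conc = _convolved_concentrations(scheme, times, irf)

    # eigenrates inside the window?
    _, lam = _eigen_terms(scheme)
    rates = -lam[-lam > 1e-12 * max(np.abs(lam).max(), 1.0)]
    t_pos = times[times > 0]
    if rates.size and not np.any((1.0 / rates >= t_pos[0] / 10)
                                 & (1.0 / rates <= t_pos[-1] * 10)):
        raise ValidationError("no scheme eigenrate falls inside the window")

    clean = spec.excited_fraction * conc @ d_spectra
    peak = np.abs(clean).max()
    if peak == 0:
        raise ValidationError("scheme/spectra produce an identically zero signal")
    scale = 1.0 / peak
    clean = clean * scale

    offset_spectrum = np.zeros_like(wl)
    if window == "fs_ns" and spec.include_pre_t0_offset:
        d_off = band_spectrum(BAND_PRESETS[spec.bands[spec.offset_label]], wl) - gs
        offset_spectrum = -spec.pre_t0_amplitude * d_off / np.abs(d_off).max()
        clean = clean + offset_spectrum[None, :]

    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_rms, size=clean.shape)

    matrix = SpectroTemporalMatrix(noisy, times, wl, window=window,
                                   kind="difference",
                                   meta={"seed": spec.seed,
                                         "noise_rms": spec.noise_rms})
    lifetimes = np.sort(1.0 / rates) if rates.size else np.array([])
    truth = {
        "scheme": scheme,
        "species": observed,
        "lifetimes": lifetimes,
        "rates": rates,
        "noiseless": clean,
        "scale": scale,
        "excited_fraction": spec.excited_fraction,
        "gs_spectrum": gs * scale,
        "species_spectra": (gs[None, :] + d_spectra) * scale,
        "difference_spectra": d_spectra * scale * spec.excited_fraction,
        "offset_spectrum": offset_spectrum,
        "branching": ({dst: k / scheme.total_rate(scheme.excited_entry)
                       for _, dst, k in scheme.out_edges(scheme.excited_entry)}
                      if scheme.out_edges(scheme.excited_entry) else {}),
    }
    return matrix, truth


def generate_photoconversion(
    n_steps: int = 20,
    conversion_per_step: float = 0.25,
    residual_gs: float = 0.02,
    noise_rms: float = 0.002,
    seed: int = 0,
    wavelengths=None,
    bands=None,
):
    """Stepwise illumination series of a two-state photoconversion.

    Step s carries a ground-state mole fraction max(residual_gs,
    (1 − conversion_per_step)^s); the spectra are the fraction-weighted dark
    and light presets plus seeded noise (OD).
    """
    if not 0 < conversion_per_step <= 1:
        raise ValidationError("conversion_per_step must lie in (0, 1]")
    if not 0 <= residual_gs < 1:
        raise ValidationError("residual_gs must lie in [0, 1)")
    wl = np.asarray(wavelengths if wavelengths is not None
                    else default_wavelengths(), dtype=float)
    bands = bands or DEFAULT_SPECIES_BANDS
    s_gs = band_spectrum(BAND_PRESETS[bands["GS"]], wl)
    s_ls = band_spectrum(BAND_PRESETS[bands["LS"]], wl)
    steps = np.arange(n_steps)
    x_gs = np.maximum(residual_gs, (1.0 - conversion_per_step) ** steps)
    clean = np.outer(x_gs, s_gs) + np.outer(1.0 - x_gs, s_ls)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_rms, size=clean.shape)
    matrix = SpectroTemporalMatrix(noisy, steps.astype(float), wl,
                                   window="steady_state", kind="absolute",
                                   meta={"seed": seed})
    truth = {"gs_fractions": x_gs, "gs_spectrum": s_gs, "ls_spectrum": s_ls,
             "residual_gs": residual_gs, "noiseless": clean}
    return matrix, truth


def generate_titration(
    kd: float,
    b0: float = 5.0,
    a0_values=None,
    noise_rms: float = 0.01,
    seed: int = 0,
    wavelengths=None,
):
    """Spectral titration of a chromophore (b0 μM) with apoprotein.

    Spectra interpolate between the free-cobalamin and bound (dark-state)
    presets with the bound fraction from the exact quadratic isotherm;
    ``noise_rms`` is relative to the peak absorbance.
    """
    if kd <= 0 or b0 <= 0:
        raise ValidationError("kd and b0 must be positive")
    a0 = np.asarray(a0_values if a0_values is not None
                    else np.linspace(0.0, 27.0, 10), dtype=float)
    wl = np.asarray(wavelengths if wavelengths is not None
                    else default_wavelengths(), dtype=float)
    s_free = band_spectrum(BAND_PRESETS["free_cbl"], wl)
    s_bound = band_spectrum(BAND_PRESETS["carh_gs"], wl)
    x_ab = binding_fraction(a0, b0, kd)
    fb = x_ab / b0
    clean = np.outer(1.0 - fb, s_free) + np.outer(fb, s_bound)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_rms * clean.max(), size=clean.shape)
    series = BindingSeries(a0, b0, noisy, wl)
    truth = {"kd": kd, "x_ab": x_ab, "bound_fraction": fb,
             "free_spectrum": s_free, "bound_spectrum": s_bound,
             "noiseless": clean}
    return series, truth


def generate_ls_transient(spec: SyntheticSpec | None = None):
    """Ultrafast dataset of the photoproduct: one 3.2 ps decay, no baseline."""
    spec = spec or SyntheticSpec()
    spec = SyntheticSpec(
        scheme=ls_photoresponse_scheme(), bands=spec.bands,
        wavelengths=spec.wavelengths, irf_fwhm=spec.irf_fwhm,
        noise_rms=spec.noise_rms, excited_fraction=spec.excited_fraction,
        seed=spec.seed, include_pre_t0_offset=False, gs_label="LS",
    )
    return generate_transient(spec, "fs_ns")
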