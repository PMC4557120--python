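"""Branched first-order kinetic schemes and target-model projection.

A :class:`KineticScheme` is a tree of first-order conversions (branching
allowed, no cycles) entered by the photoexcited species.  Its concentration
profiles have a closed eigen-decomposition form, from which a model matrix
``X`` is built that expresses each species' kinetics as a combination of the
elementary fit functions (IRF-convolved exponentials plus a step).  Projecting
the DADS of a global fit through ``X`` yields species-associated spectra (SAS)
without changing the χ² of the fit, so every candidate mechanism is judged
with the same quality of fit and discriminated purely on physicality
(non-negative spectra and concentrations).

Difference data are blind to the recovered ground state (its ΔA vanishes), so
a scheme may name its ``ground_state``; that species is excluded from the
model matrix while still participating in the kinetics and in population
conservation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .globalfit import DADSResult, ExponentialBasis, build_basis
from .io import ValidationError
from .svd import ModelMatrix

logger = logging.getLogger(__name__)


@dataclass
class KineticScheme:
    """Species, first-order rate connections and the excitation entry point.

    ``edges`` are ``(source, target, rate_s^-1)`` triples.  Species with no
    outgoing edge are sinks (terminal states such as the ground state or the
    final photoproduct).  ``ground_state`` optionally names the species whose
    difference spectrum is identically zero.
    """

    species: list
    edges: list
    excited_entry: str
    ground_state: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species labels")
        known = set(self.species)
        for src, dst, rate in self.edges:
            if src not in known or dst not in known:
                raise ValidationError(f"edge {src}->{dst} uses unknown species")
            if rate <= 0:
                raise ValidationError(f"rate of {src}->{dst} must be > 0")
        if self.excited_entry not in known:
            raise ValidationError("excited_entry not in species")
        if self.ground_state is not None and self.ground_state not in known:
            raise ValidationError("ground_state not in species")
        # no cycles: DFS from every node
        adj = {s: [] for s in self.species}
        for src, dst, _ in self.edges:
            adj[src].append(dst)
        state = {}

        def visit(node):
            state[node] = 1
            for nxt in adj[node]:
                if state.get(nxt) == 1:
                    raise ValidationError(f"cycle detected through {nxt}")
                if state.get(nxt) is None:
                    visit(nxt)
            state[node] = 2

        for s in self.species:
            if state.get(s) is None:
                visit(s)

    @property
    def sinks(self) -> list:
        out = {src for src, _, _ in self.edges}
        return [s for s in self.species if s not in out]

    @property
    def observed_species(self) -> list:
        """Species carrying a nonzero difference spectrum."""
        return [s for s in self.species if s != self.ground_state]

    def out_edges(self, species: str) -> list:
        return [(src, dst, k) for src, dst, k in self.edges if src == species]

    def total_rate(self, species: str) -> float:
        return sum(k for _, _, k in self.out_edges(species))

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix K with dc/dt = K c; columns sum to zero."""
        idx = {s: i for i, s in enumerate(self.species)}
        n = len(self.species)
        K = np.zeros((n, n))
        for src, dst, k in self.edges:
            K[idx[dst], idx[src]] += k
            K[idx[src], idx[src]] -= k
        return K

    def descendants(self, species: str) -> set:
        """All species reachable from ``species`` (excluding it)."""
        out, stack = set(), [species]
        while stack:
            for _, dst, _ in self.out_edges(stack.pop()):
                if dst not in out:
                    out.add(dst)
                    stack.append(dst)
        return out


def branching_ratios(scheme: KineticScheme, species: str) -> dict:
    """Per-channel branching ratios k_i / Σ k_out; sums to 1 exactly."""
    edges = scheme.out_edges(species)
    if not edges:
        raise ValidationError(f"{species} has no outgoing edges")
    total = sum(k for _, _, k in edges)
    return {dst: k / total for _, dst, k in edges}


def _eigen_terms(scheme: KineticScheme, perturb: float = 1e-6, _depth: int = 0):
    """Coefficients A and eigenvalues λ with c_k(t) = Σ_m A[k,m] exp(λ_m t).

    Multiple sinks legitimately share the zero eigenvalue (the matrix stays
    diagonalizable); a *defective* rate matrix — coinciding decay rates along
    one chain, which would need t·exp(−kt) terms — is handled by a small
    documented rate perturbation with a warning.
    """
    K = scheme.rate_matrix()
    lam, P = np.linalg.eig(K)
    if np.linalg.cond(P) > 1e8:
        if _depth > 6:
            raise ValidationError("rate matrix remains defective after "
                                  "perturbation")
        warnings.warn(
            "degenerate eigenrates: perturbing rates to split them",
            stacklevel=3)
        pert = KineticScheme(
            scheme.species,
            [(s, d, k * (1 + perturb * (i + 1))) for i, (s, d, k) in
             enumerate(scheme.edges)],
            scheme.excited_entry, scheme.ground_state,
        )
        return _eigen_terms(pert, perturb * 10, _depth + 1)
    c0 = np.zeros(len(scheme.species))
    c0[scheme.species.index(scheme.excited_entry)] = 1.0
    coeff = np.linalg.solve(P, c0)
    A = P * coeff[None, :]
    return np.real(A), np.real(lam)


def scheme_concentrations(scheme: KineticScheme, times) -> np.ndarray:
    """Closed-form concentrations, unit entry population at t=0.

    Returns ``(N_T, N_species)`` in ``scheme.species`` order; the total
    population (sinks included) is conserved at 1.
    """
    t = np.asarray(times, dtype=float)
    A, lam = _eigen_terms(scheme)
    return (A @ np.exp(np.outer(lam, t))).T


def scheme_to_model_matrix(
    scheme: KineticScheme,
    basis: ExponentialBasis,
    rate_tol: float = 0.01,
) -> ModelMatrix:
    """Model matrix X with ``C_observed = F_kin · X^T``.

    The scheme's nonzero eigenrates must match the basis lifetimes within
    ``rate_tol`` (relative); a zero eigenrate (population accumulating in a
    terminal species) maps onto the step column, which the basis must then
    provide.  Rows cover the observed species only; the flat-offset column of
    the fit, if any, is no part of the photocycle.
    """
    A, lam = _eigen_terms(scheme)
    observed = scheme.observed_species
    rows = [scheme.species.index(s) for s in observed]
    if len(observed) != basis.n_kinetic:
        raise ValidationError(
            f"{len(observed)} observed species but {basis.n_kinetic} kinetic "
            "basis functions; partition the scheme per time window so the "
            "counts match"
        )
    X = np.zeros((len(observed), basis.n_kinetic))
    basis_rates = 1.0 / basis.lifetimes
    scale = max(np.abs(lam).max(), 1.0)
    mismatches = []
    for m, lm in enumerate(lam):
        rate = -lm
        amp = A[rows, m]
        if rate <= 1e-12 * scale:
            if np.allclose(amp, 0, atol=1e-12):
                continue  # the conserved mode lives in the ground state only
            if not basis.has_constant:
                mismatches.append("non-decaying population needs a constant "
                                  "column in the basis")
                continue
            col = basis.n_exp
        else:
            rel = np.abs(basis_rates - rate) / rate
            j = int(np.argmin(rel)) if rel.size else 0
            if rel.size == 0 or rel[j] > rate_tol:
                mismatches.append(
                    f"eigenrate {rate:.4g}/s has no basis lifetime within "
                    f"{rate_tol:.0%}")
                continue
            col = j
        X[:, col] += amp
    if mismatches:
        raise ValidationError("scheme/basis mismatch: " + "; ".join(mismatches))
    return ModelMatrix(X, constraint_log=[
        f"observed species {observed}",
        f"basis lifetimes {basis.lifetimes.tolist()}",
    ])


@dataclass
class SASSet:
    """Species-associated spectra and concentration profiles of one model."""

    species: list
    species_spectra: np.ndarray        # absolute SAS, N_species x N_L
    difference_spectra: np.ndarray     # N_species x N_L
    concentration_profiles: np.ndarray  # N_T x N_species
    chi2: float
    scaling: float                     # excited fraction used for the lift
    wavelength_axis: np.ndarray
    time_axis: np.ndarray
    baseline_spectrum: np.ndarray | None = None


def project_to_sas(
    dads: DADSResult,
    X: ModelMatrix,
    gs_spectrum,
    excited_fraction: float,
    species: list | None = None,
) -> SASSet:
    """Rotate DADS into SAS through the model matrix; χ² is copied unchanged.

    difference-SAS = (X^T)^-1 · B over the kinetic components; absolute SAS =
    ground-state spectrum + difference-SAS / excited_fraction.  The flat
    offset row of the fit, when present, is reported as the baseline spectrum.
    """
    if not 0 < excited_fraction <= 1:
        raise ValidationError("excited_fraction must lie in (0, 1]")
    gs = np.asarray(gs_spectrum, dtype=float)
    nk = dads.basis.n_kinetic
    if X.X.shape != (nk, nk):
        raise ValidationError(
            f"model matrix {X.X.shape} does not match the {nk} kinetic "
            "components of the fit")
    B_kin = dads.B[:nk]
    diff = np.linalg.solve(X.X.T, B_kin)
    sas = gs[None, :] + diff / excited_fraction
    F = build_basis(dads.basis, dads.time_axis)[:, :nk]
    C = F @ X.X.T
    if C.min() < -1e-9 * max(1.0, abs(C).max()):
        warnings.warn("negative concentration profiles in projection",
                      stacklevel=2)
    baseline = dads.spectrum("offset") if dads.basis.has_offset else None
    labels = list(species) if species is not None else [
        f"species_{i}" for i in range(nk)]
    return SASSet(labels, sas, diff, C, dads.chi2, excited_fraction,
                  dads.wavelength_axis, dads.time_axis,
                  baseline_spectrum=baseline)


def infer_branching(
    dads: DADSResult,
    scheme: KineticScheme,
    gs_spectrum,
    excited_fraction: float,
    branch_species: str | None = None,
    gs_support: float = 0.3,
    smooth: int = 5,
    top_k: int = 5,
) -> dict:
    """Recover branching ratios from a fit via the zero-extinction constraint.

    Within one decay branch, every descendant's difference spectrum scales
    inversely with the branch fraction, so too small a fraction drives the
    absolute SAS negative at wavelengths where the intermediate does not
    absorb but the ground state does.  The estimate for each intermediate
    branch is the smallest fraction keeping all its species' SAS non-negative
    over the strong ground-state support (gs ≥ ``gs_support`` × its maximum,
    where the bound is informative and the ratio noise bounded).  Two
    noise-robustness measures temper the extreme-value bias of a raw
    maximum: spectra are smoothed by a ``smooth``-point moving average, and
    the bound is the mean of the ``top_k`` largest ratio values (the
    touch-zero region of a banded spectrum spans several wavelength bins, so
    this averages noise without eroding the bound).  The direct
    ground-state-recovery channel takes the remainder, closing the ratios to
    1.  The scheme must carry the fitted total rates; its own branch split
    only sets the reference projection.
    """
    if branch_species is None:
        branch_species = scheme.excited_entry
    ratios0 = branching_ratios(scheme, branch_species)
    gs = np.asarray(gs_spectrum, dtype=float)
    X0 = scheme_to_model_matrix(scheme, dads.basis)
    sas0 = project_to_sas(dads, X0, gs, excited_fraction,
                          species=scheme.observed_species)
    support = gs >= gs_support * gs.max()

    def smoothed(row):
        if smooth <= 1:
            return row
        kern = np.ones(smooth) / smooth
        return np.convolve(row, kern, mode="same")

    est = {}
    gs_channels = [dst for dst in ratios0 if dst == scheme.ground_state]
    for dst, frac0 in ratios0.items():
        if dst in gs_channels:
            continue
        members = [dst] + [s for s in scheme.descendants(dst)
                           if s in scheme.observed_species]
        bound = 0.0
        for s in members:
            d = smoothed(sas0.difference_spectra[
                scheme.observed_species.index(s)])
            ratio = -d[support] / (excited_fraction * gs[support])
            k = min(top_k, ratio.size)
            bound = max(bound, float(np.mean(np.sort(ratio)[-k:])))
        est[dst] = frac0 * bound if bound > 0 else frac0
    rest = max(0.0, 1.0 - sum(est.values()))
    for dst in gs_channels:
        est[dst] = rest
    if not gs_channels:
        total = sum(est.values())
        est = {k: v / total for k, v in est.items()}
    return est


def validate_model(
    candidates,
    dads: DADSResult,
    gs_spectrum,
    excited_fraction: float = 0.1,
    negativity_tol: float = 0.15,
    smooth: int = 5,
) -> list:
    """Two-step model validation: fixed-χ² projection, then physicality checks.

    Each candidate is projected through its own model matrix (χ² identical
    across candidates by construction) and scored on rate matching, SAS
    non-negativity and concentration non-negativity.  The negativity score of
    each species is its most negative smoothed SAS value relative to that
    species' own spectral scale — minor branches have noise-amplified SAS
    (amplitudes scale inversely with the branch fraction), so a per-species
    normalization separates noise excursions from structural violations.
    Returns a report ranked by physicality (fewest violations, least
    negative SAS first).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("empty candidate list")
    gs = np.asarray(gs_spectrum, dtype=float)
    reports = []
    for i, scheme in enumerate(candidates):
        rep = {"index": i, "species": scheme.species, "chi2": dads.chi2,
               "rate_match": True, "flags": []}
        try:
            X = scheme_to_model_matrix(scheme, dads.basis)
        except ValidationError as exc:
            rep["rate_match"] = False
            rep["flags"].append(str(exc))
            rep["sas_negativity"] = np.inf
            rep["conc_negativity"] = np.inf
            reports.append(rep)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sas = project_to_sas(dads, X, gs, excited_fraction,
                                 species=scheme.observed_species)
        kern = np.ones(max(smooth, 1)) / max(smooth, 1)
        neg = 0.0
        for row in sas.species_spectra:
            sm = np.convolve(row, kern, mode="same")
            scale_s = max(np.abs(sm).max(), 1e-300)
            neg = max(neg, -min(sm.min(), 0.0) / scale_s)
        rep["sas_negativity"] = neg
        rep["conc_negativity"] = float(
            -np.clip(sas.concentration_profiles, None, 0).min())
        if rep["sas_negativity"] > negativity_tol:
            rep["flags"].append("negative SAS beyond tolerance")
        if rep["conc_negativity"] > 1e-9:
            rep["flags"].append("negative concentrations")
        reports.append(rep)
    reports.sort(key=lambda r: (not r["rate_match"], len(r["flags"]),
                                r["sas_negativity"]))
    for rank, rep in enumerate(reports):
        rep["rank"] = rank
    return reports
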