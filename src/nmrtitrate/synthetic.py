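"""Synthetic titration series with known ground truth.

All generators share the fast-exchange assumption: interconverting
protonation states give a single population-weighted resonance, so the
observed shift of a probe is the mole-fraction-weighted average of its
state shifts.  That is exactly the model the downstream analyses
(semilog Henderson–Hasselbalch fit, Perrin bilinear linearization,
Gibbs-triangle distance ratios) presuppose, which makes these series
closed-loop oracles for the estimators.

Three system classes are provided:

* monoprotic — one deprotonation, every probe an affine reporter of the
  deprotonated fraction ``f = 1/(1 + 10^(pKa − pH))``;
* coupled two-site tautomeric — two deprotonation paths (O–H and N–H)
  sharing one labile proton; each of the two reporter probes follows the
  two-state response of its own site constant, so the paired-shift
  trajectory satisfies the Perrin bilinear identity exactly at zero noise
  with slope ``K_HN/K_HO``;
* sequential polyprotic ladder — N ≥ 2 stepwise dissociations with
  per-state shift maps; the diprotic three-state system is the N = 2 case,
  and the four-state case reproduces the phenomenology of systems that
  rearrange before their two deprotonations (three slope changes in the
  paired-shift diagram).

Noise model: independent Gaussian perturbations on each recorded shift
(spectrometer digital resolution) and on each pH reading (meter error).
Shifts are evaluated at the *true* pH; only the recording is noisy.
A fixed seed makes the whole output series reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import TitrationPoint, TitrationSeries

__all__ = [
    "SiteModel",
    "TautomerSystemSpec",
    "DiproticSpec",
    "NoiseSpec",
    "default_grid",
    "simulate_monoprotic",
    "simulate_tautomeric",
    "simulate_diprotic",
    "simulate_polyprotic",
]


@dataclass(frozen=True)
class SiteModel:
    """One dissociable site and the limiting shifts of its reporters.

    ``delta_acid`` holds the shifts of the fully protonated form and
    ``delta_base`` those of the deprotonated form; the two maps must cover
    the same probe set.
    """

    pKa: float
    delta_acid: Mapping[str, float]
    delta_base: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.delta_acid) != set(self.delta_base):
            raise ValueError("delta_acid and delta_base must share one probe set")
        if not self.delta_acid:
            raise ValueError("at least one probe is required")
        if not 0.0 < self.pKa < 14.0:
            raise ValueError("pKa must lie in (0, 14) so a pH grid can bracket it")


@dataclass(frozen=True)
class TautomerSystemSpec:
    """Two coupled deprotonation paths read out by two dedicated probes.

    ``pKa_HO`` governs the O–H path reported by ``probe_O`` and ``pKa_HN``
    the N–H path reported by ``probe_N``; each probe moves between its
    ``delta_start`` and ``delta_end`` entry following its own site constant
    only (pure reporters).  The derived prototropic constant is

    ``delta_K_true = K_HN / K_HO = 10**(pKa_HO - pKa_HN)``.
    """

    pKa_HO: float
    pKa_HN: float
    delta_start: Mapping[str, float]
    delta_end: Mapping[str, float]
    probe_O: str = "H6"
    probe_N: str = "H9"

    def __post_init__(self) -> None:
        if self.probe_O == self.probe_N:
            raise ValueError("probe_O and probe_N must differ")
        for probe in (self.probe_O, self.probe_N):
            if probe not in self.delta_start or probe not in self.delta_end:
                raise ValueError(f"probe {probe!r} missing from a shift map")

    @property
    def delta_K_true(self) -> float:
        """Ground-truth site-constant quotient K_HN / K_HO."""
        return 10.0 ** (self.pKa_HO - self.pKa_HN)


@dataclass(frozen=True)
class DiproticSpec:
    """Two sequential dissociations H2A → HA⁻ → A²⁻ with three state shifts."""

    pKa1: float
    pKa2: float
    delta_H2A: Mapping[str, float]
    delta_HA: Mapping[str, float]
    delta_A: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.pKa1 < self.pKa2:
            raise ValueError("pKa1 must be smaller than pKa2")
        if not set(self.delta_H2A) == set(self.delta_HA) == set(self.delta_A):
            raise ValueError("the three state shift maps must share one probe set")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement noise.

    Defaults reflect a realistic high-field setup: 0.002 ppm shift
    resolution and 0.02 pH-meter repeatability.
    """

    sigma_shift: float = 0.002
    sigma_pH: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_shift < 0 or self.sigma_pH < 0:
            raise ValueError("noise standard deviations must be non-negative")


#: Zero-noise spec, convenient for closed-loop identities.
NOISELESS = NoiseSpec(sigma_shift=0.0, sigma_pH=0.0, seed=0)


def default_grid(pKa_low: float, pKa_high: float | None = None,
                 span: float = 2.5, n: int = 25) -> np.ndarray:
    """Evenly spaced pH grid bracketing the transition(s) by ``span`` units.

    The 25-point, ±2.5-unit default covers both plateaus of a single
    transition while keeping the aliquot count in the range of a realistic
    manual titration.
    """
    if pKa_high is None:
        pKa_high = pKa_low
    return np.linspace(pKa_low - span, pKa_high + span, n)


def _emit(
    pH_grid: Sequence[float],
    probes: Sequence[str],
    shifts_fn,
    noise: NoiseSpec,
    compound: str,
) -> TitrationSeries:
    """Assemble a series: first point ``initial``, remainder ``base``."""
    pH_grid = np.asarray(pH_grid, dtype=float)
    if pH_grid.size < 2:
        raise ValueError("pH grid needs at least 2 values")
    rng = np.random.default_rng(noise.seed)
    points: list[TitrationPoint] = []
    for i, pH in enumerate(pH_grid):
        clean = shifts_fn(float(pH))
        pH_read = float(pH) + (rng.normal(0.0, noise.sigma_pH) if noise.sigma_pH else 0.0)
        observed: dict[str, float] = {}
        for probe in probes:
            value = clean[probe]
            if noise.sigma_shift:
                value += rng.normal(0.0, noise.sigma_shift)
            observed[probe] = float(value)
        points.append(
            TitrationPoint(i, "initial" if i == 0 else "base", pH_read, observed)
        )
    return TitrationSeries(compound, 296.15, points, tuple(probes))


def deprotonated_fraction(pKa: float, pH: float) -> float:
    """Two-state deprotonated mole fraction 1 / (1 + 10^(pKa − pH))."""
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def simulate_monoprotic(
    site: SiteModel, pH_grid: Sequence[float], noise: NoiseSpec = NOISELESS
) -> TitrationSeries:
    """Titration of a single two-state site.

    At ``pH == pKa`` every probe sits exactly midway between its acid and
    base limits; five units away it is within 1e-5 of the limit.
    """
    probes = tuple(sorted(site.delta_acid))

    def shifts(pH: float) -> dict[str, float]:
        f = deprotonated_fraction(site.pKa, pH)
        return {
            p: site.delta_acid[p] + f * (site.delta_base[p] - site.delta_acid[p])
            for p in probes
        }

    return _emit(pH_grid, probes, shifts, noise, f"monoprotic pKa={site.pKa:g}")


def simulate_tautomeric(
    spec: TautomerSystemSpec, pH_grid: Sequence[float], noise: NoiseSpec = NOISELESS
) -> TitrationSeries:
    """Coupled two-site system with one pure reporter per site.

    At zero noise every point satisfies the bilinear identity
    ``(δ_N − δ_N°)(δ_O^e − δ_O) = ΔK (δ_O − δ_O°)(δ_N^e − δ_N)`` exactly,
    with ``ΔK = K_HN/K_HO``.
    """
    probes = (spec.probe_O, spec.probe_N) if spec.probe_O < spec.probe_N else (
        spec.probe_N, spec.probe_O)
    pKa_of = {spec.probe_O: spec.pKa_HO, spec.probe_N: spec.pKa_HN}

    def shifts(pH: float) -> dict[str, float]:
        out = {}
        for p in probes:
            f = deprotonated_fraction(pKa_of[p], pH)
            out[p] = spec.delta_start[p] + f * (spec.delta_end[p] - spec.delta_start[p])
        return out

    name = f"tautomeric pKa_HO={spec.pKa_HO:g} pKa_HN={spec.pKa_HN:g}"
    return _emit(pH_grid, probes, shifts, noise, name)


def state_fractions(pKas: Sequence[float], pH: float) -> np.ndarray:
    """Mole fractions of the N+1 states of a sequential N-proton ladder.

    State ``j`` (j protons removed) has relative weight
    ``K1···Kj / [H⁺]^j``; computed in log10 space for stability.
    """
    pKas = np.asarray(pKas, dtype=float)
    logw = np.concatenate(([0.0], np.cumsum(pH - pKas)))
    logw -= logw.max()
    w = 10.0 ** logw
    return w / w.sum()


def simulate_polyprotic(
    pKas: Sequence[float],
    state_shifts: Sequence[Mapping[str, float]],
    pH_grid: Sequence[float],
    noise: NoiseSpec = NOISELESS,
    compound: str = "",
) -> TitrationSeries:
    """Sequential ladder of ``len(pKas)`` dissociations.

    ``state_shifts`` lists one probe→ppm map per state, most protonated
    first; it must have ``len(pKas) + 1`` entries sharing one probe set.
    Any probe may respond to every state.
    """
    pKas = list(map(float, pKas))
    if any(b <= a for a, b in zip(pKas, pKas[1:])):
        raise ValueError("pKa values must be strictly increasing")
    if len(state_shifts) != len(pKas) + 1:
        raise ValueError("need one state shift map per state (len(pKas) + 1)")
    probe_set = set(state_shifts[0])
    if any(set(m) != probe_set for m in state_shifts[1:]):
        raise ValueError("state shift maps must share one probe set")
    probes = tuple(sorted(probe_set))
    tables = {p: np.array([m[p] for m in state_shifts]) for p in probes}

    def shifts(pH: float) -> dict[str, float]:
        x = state_fractions(pKas, pH)
        return {p: float(x @ tables[p]) for p in probes}

    compound = compound or f"polyprotic pKas={','.join(f'{k:g}' for k in pKas)}"
    return _emit(pH_grid, probes, shifts, noise, compound)


def simulate_diprotic(
    spec: DiproticSpec, pH_grid: Sequence[float], noise: NoiseSpec = NOISELESS
) -> TitrationSeries:
    """Three-state diprotic titration (H2A : HA⁻ : A²⁻ = 1 : K1/[H⁺] : K1K2/[H⁺]²)."""
    return simulate_polyprotic(
        [spec.pKa1, spec.pKa2],
        [spec.delta_H2A, spec.delta_HA, spec.delta_A],
        pH_grid,
        noise,
        compound=f"diprotic pKa1={spec.pKa1:g} pKa2={spec.pKa2:g}",
    )
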