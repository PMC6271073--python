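"""Thermodynamic layer and full-pipeline orchestration.

The prototropic constant ΔK (quotient of the two site dissociation
constants) converts into

* ΔpK = −log10 ΔK — the pK difference between the two deprotonation
  paths, and
* ΔΔG° = −RT ln ΔK (kJ mol⁻¹) — the standard free-energy difference
  between the two tautomers,

and the sign of log ΔK places the shared proton: ΔK > 1 means the labile
hydrogen sits predominantly on the nitrogen (zwitterionic ⁺N–H···O⁻ form,
ΔpK and ΔΔG° negative), ΔK < 1 on the oxygen (neutral N···H–O form), and
ΔK ≈ 1 a centred proton (N···H···O).  The default temperature is
296.15 K, the condition under which the tabulated reference values of
this package's validation suite are defined.

:func:`run_pipeline` chains the whole analysis — branch selection,
δ-diagram classification, (windowed) Henderson–Hasselbalch fits,
Perrin or Polster–Lachmann ΔK, thermodynamics — into one structured,
JSON-serializable report.  The report is deterministic: identical input
and configuration give byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .io import TitrationError, TitrationSeries, select_branch
from .hh import LimitingShifts, extract_limits, fit_pka, hh_transform
from .diagram import (
    TOL_UNITY,
    DeltaDiagram,
    LinearityResult,
    build_diagram,
    estimate_vertices,
    linearity_check,
    perrin_fit,
    polster_lachmann,
)

__all__ = [
    "Constants",
    "TautomerResult",
    "PipelineConfig",
    "delta_pk",
    "delta_g",
    "classify",
    "run_pipeline",
    "report_json",
]

#: Structural formulas associated with each classification label.
STRUCTURES = {
    "proton-on-N": "+N-H···O-",
    "proton-on-O": "N···H-O",
    "shared": "N···H···O",
}


@dataclass(frozen=True)
class Constants:
    """Gas constant (J mol⁻¹ K⁻¹) and temperature (K)."""

    R: float = 8.314
    T: float = 296.15

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.R <= 0:
            raise ValueError("gas constant must be positive")


def delta_pk(delta_K: float) -> float:
    """ΔpK = −log10 ΔK.  Negative when the proton favours nitrogen."""
    if delta_K <= 0:
        raise ValueError("delta_K must be positive")
    return -math.log10(delta_K)


def delta_g(delta_K: float, constants: Constants = Constants()) -> float:
    """ΔΔG° = −RT ln ΔK in kJ mol⁻¹."""
    if delta_K <= 0:
        raise ValueError("delta_K must be positive")
    return -constants.R * constants.T * math.log(delta_K) / 1000.0


def classify(
    delta_K: float, stderr: float | None = None, tol_unity: float = TOL_UNITY
) -> tuple[str, bool]:
    """Place the labile proton from ΔK.

    Returns ``(label, near_unity)``.  The near-unity flag is raised when
    |ΔK − 1| ≤ max(tol_unity, 2·stderr): within that band the data cannot
    distinguish the system from a centred proton.
    """
    if delta_K <= 0:
        raise ValueError("delta_K must be positive")
    band = max(tol_unity, 2.0 * stderr) if stderr is not None else tol_unity
    near_unity = abs(delta_K - 1.0) <= band
    if delta_K > 1.0:
        label = "proton-on-N"
    elif delta_K < 1.0:
        label = "proton-on-O"
    else:
        label = "shared"
    return label, near_unity


@dataclass(frozen=True)
class TautomerResult:
    """ΔK with its derived thermodynamics and classification."""

    delta_K: float
    delta_K_stderr: float | None
    delta_pK: float
    delta_delta_G: float         # kJ/mol
    classification: str
    structure: str
    near_unity: bool
    method: str                  # "perrin" or "polster-lachmann"


def tautomer_result(
    delta_K: float,
    method: str,
    stderr: float | None = None,
    constants: Constants = Constants(),
) -> TautomerResult:
    label, near_unity = classify(delta_K, stderr)
    return TautomerResult(
        delta_K=delta_K,
        delta_K_stderr=stderr,
        delta_pK=delta_pk(delta_K),
        delta_delta_G=delta_g(delta_K, constants),
        classification=label,
        structure=STRUCTURES[label],
        near_unity=near_unity,
        method=method,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration for :func:`run_pipeline`.

    ``hh_probe`` defaults to ``probe_y`` (the nitrogen-side reporter);
    ``method`` may be ``auto`` (0 breakpoints → Perrin, ≥ 1 →
    Polster–Lachmann), ``perrin`` or ``polster-lachmann``.
    """

    temperature_K: float = 296.15
    gas_constant: float = 8.314
    probe_x: str = "H6"
    probe_y: str = "H9"
    hh_probe: str | None = None
    method: str = "auto"
    plateau_points: int = 3
    branches: tuple[str, ...] = ("initial", "base")
    max_breaks: int = 2
    start_anchor: tuple[float, float] | None = None
    end_anchor: tuple[float, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("auto", "perrin", "polster-lachmann"):
            raise ValueError(f"unknown method {self.method!r}")

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        kwargs = dict(data)
        if "branches" in kwargs:
            kwargs["branches"] = tuple(kwargs["branches"])
        for key in ("start_anchor", "end_anchor"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_json(report: Mapping[str, Any]) -> str:
    """Canonical JSON rendering of a pipeline report (deterministic)."""
    return json.dumps(_jsonable(dict(report)), sort_keys=True, indent=2)


def _window_limits(
    sub: TitrationSeries,
    probe: str,
    n_plateau: int,
    inner_low: float | None,
    inner_high: float | None,
) -> LimitingShifts:
    """Limiting shifts of a pH window.

    Ends that border another transition take the vertex estimate
    (``inner_low``/``inner_high``) instead of a plateau mean — the
    intermediate species never develops a plateau of its own.
    """
    values = [s for _, s in sub.shifts_for(probe)]
    n_edge = min(n_plateau, max(1, len(values) // 3))
    low = inner_low if inner_low is not None else float(np.mean(values[:n_edge]))
    high = inner_high if inner_high is not None else float(np.mean(values[-n_edge:]))
    lo, hi = sorted((low, high))
    return LimitingShifts(lo, hi, probe, n_edge)


def run_pipeline(
    series: TitrationSeries, config: PipelineConfig = PipelineConfig()
) -> dict[str, Any]:
    """Execute the full analysis and return one structured report.

    Stage failures are recorded under ``errors`` (keyed by stage name)
    with ``None`` placeholders for the results they prevented; a report
    with an empty ``errors`` mapping is a full success.
    """
    constants = Constants(R=config.gas_constant, T=config.temperature_K)
    hh_probe = config.hh_probe or config.probe_y
    report: dict[str, Any] = {
        "compound": series.compound,
        "config": config,
        "constants": constants,
        "hh": None,
        "diagram": None,
        "method": None,
        "perrin": None,
        "polster_lachmann": None,
        "tautomer": None,
        "errors": {},
    }

    selected = select_branch(series, config.branches)

    diagram: DeltaDiagram | None = None
    linearity: LinearityResult | None = None
    try:
        diagram = build_diagram(
            selected, config.probe_x, config.probe_y,
            config.start_anchor, config.end_anchor,
        )
        max_breaks = config.max_breaks
        if max_breaks >= 2 and len(diagram) < 6:
            max_breaks = 1
        if max_breaks >= 1 and len(diagram) < 4:
            max_breaks = 0
        linearity = linearity_check(diagram, max_breaks=max_breaks)
        report["diagram"] = {
            "probe_x": config.probe_x,
            "probe_y": config.probe_y,
            "n_points": len(diagram),
            "breakpoints": linearity.selected,
            "total_turn_deg": math.degrees(linearity.total_turn),
            "vertex_indices": list(linearity.model.vertices),
        }
    except (TitrationError, ValueError) as exc:
        report["errors"]["diagram"] = str(exc)

    # ---- Henderson–Hasselbalch stage (windowed when transitions > 1) ----
    try:
        report["hh"] = _hh_stage(selected, hh_probe, config, diagram, linearity)
    except (TitrationError, ValueError) as exc:
        report["errors"]["hh"] = str(exc)

    # ---- ΔK stage -------------------------------------------------------
    delta_K = stderr = None
    method = config.method
    try:
        if diagram is None or linearity is None:
            raise TitrationError("diagram stage failed")
        if method == "auto":
            method = "perrin" if linearity.selected == 0 else "polster-lachmann"
        report["method"] = method
        if method == "perrin":
            fit = perrin_fit(diagram)
            report["perrin"] = fit
            delta_K, stderr = fit.delta_K, fit.slope_stderr
        else:
            model = (
                linearity.model
                if linearity.selected >= 1
                else linearity.models.get(1)
            )
            if model is None:
                raise TitrationError("no piecewise model with a vertex available")
            pl = polster_lachmann(diagram, model)
            report["polster_lachmann"] = pl
            delta_K = pl.delta_K
    except (TitrationError, ValueError) as exc:
        report["errors"]["delta_K"] = str(exc)

    # ---- thermodynamics --------------------------------------------------
    if delta_K is not None:
        try:
            report["tautomer"] = tautomer_result(delta_K, method, stderr, constants)
        except (TitrationError, ValueError) as exc:
            report["errors"]["thermo"] = str(exc)

    return report


def _hh_stage(
    series: TitrationSeries,
    probe: str,
    config: PipelineConfig,
    diagram: DeltaDiagram | None,
    linearity: LinearityResult | None,
) -> list[dict[str, Any]]:
    """One semilog fit per transition window.

    With no diagram information (or no breakpoints) the whole series is a
    single window with plateau-mean limits.  With k ≥ 1 breakpoints the
    series splits at the vertex points; window ends shared with another
    transition take the vertex intersection as their limiting shift.
    """
    n_windows = 1
    boundaries: list[int] = []
    vertex_shift: list[float | None] = []
    if diagram is not None and linearity is not None and linearity.selected >= 1:
        n_windows = linearity.selected + 1
        boundaries = [int(diagram.source_index[v]) for v in linearity.model.vertices]
        coord = None
        if probe == diagram.probe_x:
            coord = 0
        elif probe == diagram.probe_y:
            coord = 1
        for est, v in zip(estimate_vertices(diagram, linearity.model),
                          linearity.model.vertices):
            if coord is not None:
                vertex_shift.append(float(est[coord]))
            else:
                pt = series.points[int(diagram.source_index[v])]
                vertex_shift.append(pt.shifts.get(probe))

    edges = [0] + boundaries + [len(series.points) - 1]
    fits: list[dict[str, Any]] = []
    for w in range(n_windows):
        lo, hi = edges[w], edges[w + 1]
        sub = dataclasses.replace(series, points=series.points[lo : hi + 1])
        inner_low = vertex_shift[w - 1] if w > 0 else None
        inner_high = vertex_shift[w] if w < n_windows - 1 else None
        entry: dict[str, Any] = {"window": [lo, hi], "probe": probe}
        try:
            if n_windows == 1:
                limits = extract_limits(sub, probe, config.plateau_points)
            else:
                if not sub.shifts_for(probe):
                    raise TitrationError(f"probe {probe!r} absent in window")
                limits = _window_limits(
                    sub, probe, config.plateau_points, inner_low, inner_high
                )
            entry["limits"] = limits
            entry["fit"] = fit_pka(hh_transform(sub, probe, limits))
        except (TitrationError, ValueError) as exc:
            entry["error"] = str(exc)
            if n_windows == 1:
                raise
        fits.append(entry)
    return fits
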