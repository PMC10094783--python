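"""Tunable tolerances and pipeline options, overridable from YAML.

A config file may hold a ``pipeline`` section (fields of
:class:`PipelineConfig`) and a ``phantom`` section (field overrides for
:class:`~scapulometry.phantom.PhantomParams`)::

    pipeline:
      include_glenoid_in_plane: true
      sphere_coverage_min_deg: 25
    phantom:
      ridge_bow: 4.0
      noise_sd: 0.2
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .phantom import PhantomParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Measurement-pipeline options.

    include_glenoid_in_plane
        Add the glenoid points to the scapular-plane fit.  Off by
        default: on phantoms the blade alone defines the ground-truth
        plane, and a small tilted glenoid patch pulls the fitted plane
        toward its own orientation.
    sphere_max_iter / sphere_step_tol
        Gauss-Newton iteration cap and convergence step (mm) for the
        geometric sphere refinement.
    sphere_coverage_min_deg
        Minimum angular coverage of a spherical cap before the fit is
        flagged ill-conditioned (shallow glenoid patches barely
        constrain the radius).
    frame_min_axis_plane_angle_deg
        Transverse axes closer than this to the scapular-plane normal
        are rejected as degenerate.
    report_decimals
        Display rounding for angles/percentages; full precision is kept
        internally.
    """

    include_glenoid_in_plane: bool = False
    sphere_max_iter: int = 100
    sphere_step_tol: float = 1e-10
    sphere_coverage_min_deg: float = 20.0
    frame_min_axis_plane_angle_deg: float = 5.0
    report_decimals: int = 1

    def sphere_kwargs(self) -> dict:
        return {
            "max_iter": self.sphere_max_iter,
            "step_tol": self.sphere_step_tol,
            "coverage_min_deg": self.sphere_coverage_min_deg,
        }

    def pipeline_kwargs(self) -> dict:
        return {
            "include_glenoid_in_plane": self.include_glenoid_in_plane,
            "min_axis_plane_angle_deg": self.frame_min_axis_plane_angle_deg,
            "sphere_kwargs": self.sphere_kwargs(),
        }


def load_config(path: str | Path | None) -> tuple[PipelineConfig, PhantomParams]:
    """Load (pipeline config, phantom defaults) from a YAML file.

    ``path=None`` returns the package defaults.
    """
    pipeline = PipelineConfig()
    phantom = PhantomParams()
    if path is None:
        return pipeline, phantom
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    pipe_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key, value in (raw.get("pipeline") or {}).items():
        if key not in pipe_fields:
            raise ValueError(f"{path}: unknown pipeline option {key!r}")
        setattr(pipeline, key, value)
    phantom_fields = {f.name for f in dataclasses.fields(PhantomParams)}
    overrides = raw.get("phantom") or {}
    bad = set(overrides) - phantom_fields
    if bad:
        raise ValueError(f"{path}: unknown phantom option(s) {sorted(bad)}")
    phantom = dataclasses.replace(phantom, **overrides)
    phantom.validate()
    return pipeline, phantom
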