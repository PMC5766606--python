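"""YAML configuration loading for the simulate/fit/stats pipeline.

A config file is a flat mapping of sections, each mirroring a dataclass:

    display: {screen_width_cm: 36.8, ...}
    carpet:  {occluder_side_deg: 6.7, ...}
    design:  {trial_dur_s: 30, ...}
    grid:    {x_max_deg: 8.5, cell_deg: 0.1, ...}
    hrf:     {peak_delay_s: 6.0, ...}
    noise:   {white_sd: 5.5, ar1_rho: 0.3, ...}
    search:  {x0: [...], y0: [...], sigma: [...]}
    simulate: {n_per_area: 100, n_runs: 4, band_fraction: 0.8, ...}

Missing sections and keys fall back to the package defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .fitting import SearchGrid
from .geometry import CarpetSpec, DisplayGeometry, RunDesign, VisualFieldGrid
from .model import HRFSpec
from .simulate import NoiseModel

_SECTIONS = {
    "display": DisplayGeometry,
    "carpet": CarpetSpec,
    "design": RunDesign,
    "grid": VisualFieldGrid,
    "hrf": HRFSpec,
    "noise": NoiseModel,
}


def load_config(path: str | Path | None = None) -> dict:
    """Parse a YAML config into instantiated component specs.

    Returns a dict with keys display, carpet, design, grid, hrf, noise,
    search, and simulate (a plain dict of generator options).
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    out: dict = {}
    for key, cls in _SECTIONS.items():
        section = dict(raw.get(key) or {})
        if key == "design" and "trial_sequence" in section:
            section["trial_sequence"] = tuple(section["trial_sequence"])
        out[key] = cls(**section)
    search = dict(raw.get("search") or {})
    out["search"] = SearchGrid(**{k: tuple(v) for k, v in search.items()})
    out["simulate"] = dict(raw.get("simulate") or {})
    return out
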