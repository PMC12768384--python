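"""Named defaults and YAML config loading for the command-line interface."""
from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    "beta": 10.0,
    "tau": 0.2,
    "magnification": 1.4,
    "hybrid_weight": 0.05,
    "behavior_threshold": 0.5,
    "short_locomotion_seconds": 2.0,
    "short_pause_seconds": 5.0,
    "dwell_bin_width": 0.1,
    "dwell_min": 0.05,
    "pair_corr_threshold": 0.7,
    "influence_window_seconds": 10.0,
    "stimulus_amplitude": 2.0,
    "stimulus_window_minutes": 5.0,
    "forward_speed_mm_s": 0.15,
    "reversal_speed_mm_s": 0.075,
    "p_omega": 0.35,
    "rel_tol": 1e-8,
    "abs_tol": 1e-10,
}


def load_config(path=None) -> dict:
    """Defaults merged with the YAML file at ``path`` (if given)."""
    cfg = dict(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg.update(loaded)
    return cfg
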