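"""Flat key-value run configuration.

Plain-text INI-style files with one section per module; every tunable
from the pipeline's design decisions is exposed.  Unknown sections or
keys are errors, so typos fail loudly instead of silently falling back to
defaults.
"""

from __future__ import annotations

import configparser
from dataclasses import fields

from .preprocess import PreprocessConfig
from .synthetic import KernelSpec, SimulationConfig

__all__ = ["RunConfig", "load_config"]

_DECODING_DEFAULTS = {
    "window_width": 45.0,
    "overlap": 30.0,
    "start_bound": 500.0,
    "fs": 64.0,
    "lambda_low_exp": -6,
    "lambda_high_exp": 6,
    "lambda_step_exp": 2,
    "segment": 60.0,
    "mode": "subject_independent",
}

_EVALUATION_DEFAULTS = {
    "analysis_lo": 120.0,
    "analysis_hi": 270.0,
    "alpha": 0.05,
    "n_perm": 10000,
    "segment_length": 120.0,
}


class RunConfig:
    """Parsed configuration for one pipeline run."""

    def __init__(
        self,
        synthetic: SimulationConfig,
        preprocess: PreprocessConfig,
        decoding: dict,
        evaluation: dict,
    ) -> None:
        self.synthetic = synthetic
        self.preprocess = preprocess
        self.decoding = decoding
        self.evaluation = evaluation


def _coerce(value: str, like):
    if isinstance(like, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(like, int):
        return int(value)
    if isinstance(like, float):
        return float(value)
    if isinstance(like, tuple):
        parts = [float(v) for v in value.replace(",", " ").split()]
        return tuple(parts)
    return value


def load_config(path: str | None = None) -> RunConfig:
    """Parse a config file; a missing path yields all defaults."""
    sim_kwargs: dict = {}
    kernel_kwargs: dict = {}
    pre_kwargs: dict = {}
    dec = dict(_DECODING_DEFAULTS)
    ev = dict(_EVALUATION_DEFAULTS)

    if path is not None:
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(f"config file not found: {path}")

        sim_fields = {f.name: f for f in fields(SimulationConfig) if f.name != "kernel"}
        kernel_fields = {f.name: f for f in fields(KernelSpec)}
        pre_fields = {f.name: f for f in fields(PreprocessConfig)}
        known = {
            "synthetic": sim_fields,
            "kernel": kernel_fields,
            "preprocess": pre_fields,
            "decoding": dec,
            "evaluation": ev,
        }
        for section in parser.sections():
            if section not in known:
                raise ValueError(f"unknown config section [{section}]")
            for key, value in parser[section].items():
                if key not in known[section]:
                    raise ValueError(f"unknown key {key!r} in section [{section}]")
                if section == "synthetic":
                    defaults = SimulationConfig()
                    sim_kwargs[key] = _coerce(value, getattr(defaults, key))
                elif section == "kernel":
                    defaults = KernelSpec()
                    kernel_kwargs[key] = _coerce(value, getattr(defaults, key))
                elif section == "preprocess":
                    defaults = PreprocessConfig()
                    pre_kwargs[key] = _coerce(value, getattr(defaults, key))
                elif section == "decoding":
                    dec[key] = _coerce(value, _DECODING_DEFAULTS[key])
                else:
                    ev[key] = _coerce(value, _EVALUATION_DEFAULTS[key])

    synthetic = SimulationConfig(kernel=KernelSpec(**kernel_kwargs), **sim_kwargs)
    preprocess = PreprocessConfig(**pre_kwargs)
    return RunConfig(synthetic, preprocess, dec, ev)
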