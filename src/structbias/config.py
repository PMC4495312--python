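"""YAML/JSON simulation configuration loading and validation."""
from __future__ import annotations

from pathlib import Path

import yaml

from .population import (
    K_LEVELS,
    N_LEVELS,
    RHO2_YY_LEVELS,
    RHO_XX_LEVELS,
    ParameterError,
    design_grid,
)
from .simulation import (
    DEFAULT_POPULATION_SIZE,
    DEFAULT_REPS,
    DEFAULT_SEED,
    SimConfig,
)

__all__ = ["load_config", "build_config"]

_TOP_KEYS = {"reps", "seed", "mode", "population_size", "cells"}
_CELL_KEYS = {"k", "rho2_yy", "rho_xx", "n"}
_CELL_ALLOWED = {
    "k": K_LEVELS,
    "rho2_yy": RHO2_YY_LEVELS,
    "rho_xx": RHO_XX_LEVELS,
    "n": N_LEVELS,
}


def build_config(raw: dict | None) -> SimConfig:
    """Validated :class:`SimConfig` from a raw mapping, defaults filled.

    Unknown keys are rejected by name; cell filters must use grid levels.
    """
    raw = dict(raw or {})
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ParameterError(
            f"unknown config key(s) {sorted(unknown)}; "
            f"allowed: {sorted(_TOP_KEYS)}"
        )
    reps = raw.get("reps", DEFAULT_REPS)
    if not isinstance(reps, int) or reps < 1:
        raise ParameterError(f"reps must be a positive integer, got {reps!r}")
    seed = raw.get("seed", DEFAULT_SEED)
    if not isinstance(seed, int):
        raise ParameterError(f"seed must be an integer, got {seed!r}")
    mode = raw.get("mode", "finite")
    if mode not in ("finite", "direct"):
        raise ParameterError(
            f"mode must be 'finite' or 'direct', got {mode!r}"
        )
    size = raw.get("population_size", DEFAULT_POPULATION_SIZE)
    if not isinstance(size, int) or size < 1:
        raise ParameterError(
            f"population_size must be a positive integer, got {size!r}"
        )

    cells = None
    filt = raw.get("cells")
    if filt is not None:
        if not isinstance(filt, dict):
            raise ParameterError("cells must be a mapping of factor -> levels")
        unknown = set(filt) - _CELL_KEYS
        if unknown:
            raise ParameterError(
                f"unknown cells key(s) {sorted(unknown)}; "
                f"allowed: {sorted(_CELL_KEYS)}"
            )
        for key, values in filt.items():
            bad = [v for v in values if v not in _CELL_ALLOWED[key]]
            if bad:
                raise ParameterError(
                    f"cells.{key} values {bad} are not grid levels "
                    f"{list(_CELL_ALLOWED[key])}"
                )
        cells = tuple(
            c
            for c in design_grid()
            if ("k" not in filt or c.spec.k in filt["k"])
            and ("rho2_yy" not in filt or c.spec.rho2_yy in filt["rho2_yy"])
            and ("rho_xx" not in filt or c.spec.rho_xx in filt["rho_xx"])
            and ("n" not in filt or c.n in filt["n"])
        )
        if not cells:
            raise ParameterError("cells filter selects no design cells")
    return SimConfig(
        reps=reps,
        seed=seed,
        population_mode=mode,
        population_size=size,
        cells=cells,
    )


def load_config(path: str | Path) -> SimConfig:
    """Load and validate a YAML (or JSON) simulation config file.

    An empty file yields the full default study configuration.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError("config must be a mapping at the top level")
    return build_config(raw)
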