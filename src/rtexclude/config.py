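"""Study configuration.

``SimConfig`` carries every knob of the simulation study; the defaults are
the full study design (101 mu-differences x 5000 pairs per difference, both
contamination approaches, all ten exclusion rules, alpha = 0.05).  Configs
can be loaded from a YAML file; an empty file yields the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import yaml

from .contamination import APPROACHES
from .distributions import DEFAULT_DIFF_GRID
from .exclusion import METHOD_NAMES

__all__ = ["SimConfig", "load_config"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run.

    Attributes
    ----------
    diff_grid : sequence of float
        Population mu-differences in ms (default 0..100 in 1 ms steps).
    reps_per_diff : int
        Simulated pairs per difference level per approach (default 5000).
    approaches : tuple of str
        Subset of {"tails", "overlap"}.
    methods : tuple of str
        Subset of the ten exclusion-rule names, in application order.
    master_seed : int
        Seed of the run; each (approach, diff, repetition) iteration uses a
        substream derived from it, so any single iteration is reproducible
        in isolation.
    alpha : float
        Two-sided significance level.
    min_n_after_exclusion : int
        Minimum post-exclusion sample size per condition for the t-test to
        be attempted; below it the iteration is recorded as non-significant
        for that method and counted.
    output_dir : Path
        Destination for the CSV tables written by the CLI.
    """

    diff_grid: Sequence[float] = DEFAULT_DIFF_GRID
    reps_per_diff: int = 5000
    approaches: tuple[str, ...] = APPROACHES
    methods: tuple[str, ...] = METHOD_NAMES
    master_seed: int = 0
    alpha: float = 0.05
    min_n_after_exclusion: int = 3
    output_dir: Path = Path("rtexclude_output")

    def __post_init__(self) -> None:
        object.__setattr__(self, "diff_grid", tuple(float(d) for d in self.diff_grid))
        object.__setattr__(self, "approaches", tuple(self.approaches))
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "output_dir", Path(self.output_dir))
        if not self.diff_grid:
            raise ValueError("diff_grid must be non-empty")
        if any(d < 0 for d in self.diff_grid):
            raise ValueError("diff values must be non-negative")
        if self.reps_per_diff < 1:
            raise ValueError("reps_per_diff must be >= 1")
        if not self.approaches:
            raise ValueError("approaches must be non-empty")
        unknown = set(self.approaches) - set(APPROACHES)
        if unknown:
            raise ValueError(f"unknown approaches: {sorted(unknown)}")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ValueError(
                f"unknown methods: {sorted(unknown)}; valid names are {METHOD_NAMES}"
            )
        if len(set(self.methods)) != len(self.methods):
            raise ValueError("methods must not repeat")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_n_after_exclusion < 2:
            raise ValueError("min_n_after_exclusion must be >= 2")

    def with_overrides(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def load_config(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file.

    Missing keys fall back to the study defaults; unknown keys raise a
    descriptive error.  An empty file yields the full default design.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping, got {type(raw)}")
    known = {f.name for f in fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys are {sorted(known)}"
        )
    if "methods" in raw and isinstance(raw["methods"], list):
        # YAML 1.1 reads a bare `no` as boolean False; restore the rule name
        raw["methods"] = ["no" if m is False else m for m in raw["methods"]]
    return SimConfig(**raw)
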