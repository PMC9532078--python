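"""Repeated-run benchmark experiments comparing the optimizer variants.

A variant is either the baseline swarm (``"ssa"``) or the improved loop
driven by one of the nine chaotic maps.  Each (function, variant) cell is
run with a paired seed list and summarized by the best, mean and standard
deviation of the final best fitness over the repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .benchmarks import BenchmarkFunction, evaluate, get_function
from .chaos import MAP_NAMES, make_map
from .optimizer import OptimizerResult, SparrowConfig, run_cgssa, run_ssa

__all__ = ["RunSummary", "VARIANTS", "run_experiment", "compare_variants", "summaries_frame"]

VARIANTS = ("ssa",) + MAP_NAMES


@dataclass(frozen=True)
class RunSummary:
    function: str
    variant: str
    repeats: int
    best_value: float
    mean_value: float
    std_value: float

    def __post_init__(self) -> None:
        assert self.best_value <= self.mean_value + 1e-300
        assert self.std_value >= 0.0


def _make_objective(fn: BenchmarkFunction, rng: np.random.Generator):
    if fn.stochastic:
        return lambda x: evaluate(fn, x, rng)
    return lambda x: evaluate(fn, x)


def run_experiment(
    fn: BenchmarkFunction | str,
    variant: str,
    repeats: int = 20,
    base_seed: int = 1,
    pop_size: int = 30,
    max_iter: int = 500,
    discoverer_frac: float = 0.2,
    scout_frac: float = 0.2,
    ddof: int = 0,
) -> tuple[RunSummary, list[np.ndarray]]:
    """Run one (function, variant) cell; returns the summary and all traces.

    Repeat r uses seed ``base_seed + r`` so that different variants run on
    identical seed lists and comparisons are paired.  ``ddof=0`` (population
    standard deviation) is the default summary convention.
    """
    if isinstance(fn, str):
        fn = get_function(fn)
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; known: {VARIANTS}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    finals = np.empty(repeats)
    traces: list[np.ndarray] = []
    for r in range(repeats):
        seed = base_seed + r
        cfg = SparrowConfig(
            dim=fn.dimension,
            lower_bound=fn.lower_bound,
            upper_bound=fn.upper_bound,
            pop_size=pop_size,
            max_iter=max_iter,
            discoverer_frac=discoverer_frac,
            scout_frac=scout_frac,
            chaotic_map=None if variant == "ssa" else make_map(variant),
            seed=seed,
        )
        noise_rng = np.random.default_rng(seed + 10_000_019)
        objective = _make_objective(fn, noise_rng)
        result: OptimizerResult = (
            run_ssa(objective, cfg) if variant == "ssa" else run_cgssa(objective, cfg)
        )
        finals[r] = result.best_fitness
        traces.append(result.trace)
    summary = RunSummary(
        function=fn.label,
        variant=variant,
        repeats=repeats,
        best_value=float(np.min(finals)),
        mean_value=float(np.mean(finals)),
        std_value=float(np.std(finals, ddof=ddof)),
    )
    return summary, traces


def compare_variants(
    functions: Sequence[BenchmarkFunction | str],
    variants: Sequence[str],
    repeats: int = 20,
    base_seed: int = 1,
    trace_dir: Optional[Path] = None,
    **config_kwargs,
) -> pd.DataFrame:
    """Grid of run_experiment cells as a tidy frame.

    One row per (function, variant); ``is_best`` flags the variant(s)
    attaining the minimal best_value within each function.  When
    ``trace_dir`` is given, every convergence trace is written to
    ``<fn>_<variant>_<rep>.csv``.
    """
    if not functions or not variants:
        raise ValueError("functions and variants must be non-empty")
    summaries = []
    for fn in functions:
        for variant in variants:
            summary, traces = run_experiment(
                fn, variant, repeats=repeats, base_seed=base_seed, **config_kwargs
            )
            summaries.append(summary)
            if trace_dir is not None:
                trace_dir = Path(trace_dir)
                trace_dir.mkdir(parents=True, exist_ok=True)
                for r, trace in enumerate(traces):
                    out = trace_dir / f"{summary.function}_{variant}_{r}.csv"
                    pd.DataFrame(
                        {"iteration": np.arange(1, len(trace) + 1), "best_fitness": trace}
                    ).to_csv(out, index=False)
    frame = summaries_frame(summaries)
    frame["is_best"] = frame.groupby("function")["best_value"].transform(
        lambda v: v == v.min()
    )
    return frame


def summaries_frame(summaries: Iterable[RunSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "function": s.function,
                "variant": s.variant,
                "repeats": s.repeats,
                "best_value": s.best_value,
                "mean_value": s.mean_value,
                "std_value": s.std_value,
            }
            for s in summaries
        ]
    )


def format_scientific(frame: pd.DataFrame) -> pd.DataFrame:
    """Value columns rendered to 4 significant digits in scientific style."""
    out = frame.copy()
    for col in ("best_value", "mean_value", "std_value"):
        out[col] = out[col].map(lambda v: f"{v:.3E}")
    return out
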