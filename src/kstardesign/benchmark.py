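"""Estimator-accuracy benchmark: EWAK* windows vs ε-approximate K* scores.

Generates seeded synthetic problems, FRIES-prunes each, and scores every
surviving sequence with the ε-approximate estimator and with the
energy-window estimator at one or more windows, combining states
identically.  Reports the maximum and mean absolute per-sequence difference
in log10 K* plus minimized-conformation counts — the desk-scale analogue of
comparing an energy-window design run against a reference ε run.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence as TSequence

from .fries import FriesParams, fries_prune_problem
from .kstar import PfuncCache, kstar_score
from .synthgen import GeneratorParams, generate_problem

__all__ = ["compare_window_vs_eps"]


def compare_window_vs_eps(
    seeds: Iterable[int],
    fries_params: FriesParams,
    epsilon: float,
    windows: TSequence[float],
    base_params: GeneratorParams | None = None,
) -> dict:
    """Max/mean |Δ log10 K*| between the window and ε estimators.

    One problem per seed (default benchmark generator profile unless
    ``base_params`` overrides it); scores are compared on the FRIES
    survivors of each problem.
    """
    if base_params is None:
        base_params = GeneratorParams()
    diffs: dict[float, list[float]] = {w: [] for w in windows}
    n_min_eps: list[int] = []
    n_min_win: dict[float, list[int]] = {w: [] for w in windows}
    n_problems = 0
    for seed in seeds:
        n_problems += 1
        problem = generate_problem(replace(base_params, seed=int(seed)))
        survivors, _ = fries_prune_problem(problem, fries_params)
        cache: PfuncCache = {}
        for seq in sorted(survivors):
            s_eps = kstar_score(
                problem, seq, method="eps", epsilon=epsilon, cache=cache
            )
            n_min_eps.append(s_eps.pfuncs["complex"].n_minimized)
            for w in windows:
                s_win = kstar_score(
                    problem, seq, method="window", w_conf=w, cache=cache
                )
                diffs[w].append(abs(s_win.log10_score - s_eps.log10_score))
                n_min_win[w].append(s_win.pfuncs["complex"].n_minimized)
    n_seqs = len(n_min_eps)

    def _mean(xs):
        return sum(xs) / len(xs) if xs else float("nan")

    all_diffs = [d for w in windows for d in diffs[w]]
    return {
        "epsilon": epsilon,
        "n_problems": n_problems,
        "n_sequences": n_seqs,
        "mean_n_minimized_complex_eps": _mean(n_min_eps),
        "per_window": {
            str(w): {
                "max_abs_diff_log10": max(diffs[w]) if diffs[w] else float("nan"),
                "mean_abs_diff_log10": _mean(diffs[w]),
                "mean_n_minimized_complex": _mean(n_min_win[w]),
            }
            for w in windows
        },
        "max_abs_diff_log10": max(all_diffs) if all_diffs else float("nan"),
        "mean_abs_diff_log10": _mean(all_diffs),
    }
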