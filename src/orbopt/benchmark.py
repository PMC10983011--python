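"""Benchmark statistics: iteration-count summaries and energy comparisons.

Mirrors the reporting format of SCF-convergence benchmarks: per-set mean and
standard deviation of post-startup iteration counts (over converged runs
only), the number of runs needing more than 120 iterations, the number not
converged within the 400-iteration cap, five-number box-and-whisker summaries
with the 1.5*IQR whisker rule, and pairwise converged-energy differences
flagged above 5e-7 E_h.

Quartiles use linear interpolation (the common "type 7" convention).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .driver import METHODS, IterationTrace, RunConfig, optimize
from .fixtures import make_fixture

__all__ = [
    "count_statistics",
    "box_statistics",
    "energy_differences",
    "benchmark",
    "BenchmarkSummary",
]

LONG_RUN_THRESHOLD = 120
ENERGY_DIFF_THRESHOLD = 5e-7


def count_statistics(counts, converged=None) -> dict:
    """Mean/SD (converged runs only) plus long-run and failure counts."""
    counts = np.asarray(counts, dtype=float)
    if converged is None:
        converged = np.ones(counts.shape, dtype=bool)
    converged = np.asarray(converged, dtype=bool)
    ok = counts[converged]
    return {
        "n": int(counts.size),
        "n_converged": int(ok.size),
        "mean": float(np.mean(ok)) if ok.size else float("nan"),
        "sd": float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0,
        "n_over_120": int(np.sum(ok > LONG_RUN_THRESHOLD)),
        "n_not_converged": int(np.sum(~converged)),
    }


def box_statistics(counts) -> dict:
    """Five-number summary with 1.5*IQR whiskers ending on data points."""
    x = np.sort(np.asarray(counts, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = (float(np.percentile(x, p, method="linear")) for p in (25, 50, 75))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    whisker_lo = float(inside[0]) if inside.size else q1
    whisker_hi = float(inside[-1]) if inside.size else q3
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return {
        "q1": q1,
        "median": med,
        "q3": q3,
        "iqr": iqr,
        "whisker_lo": whisker_lo,
        "whisker_hi": whisker_hi,
        "outliers": [float(v) for v in outliers],
    }


def energy_differences(energies: dict, reference: str, threshold: float = ENERGY_DIFF_THRESHOLD):
    """Per-method differences ``E_ref - E_other``, flagged above the threshold."""
    if reference not in energies:
        raise KeyError(f"reference method {reference!r} not in results")
    out = {}
    for method, e in energies.items():
        if method == reference:
            continue
        diff = energies[reference] - e
        out[method] = {"difference": float(diff), "flagged": bool(abs(diff) > threshold)}
    return out


@dataclass
class BenchmarkSummary:
    methods: list[str]
    fixtures: list[str]
    statistics: dict = field(default_factory=dict)  # method -> count_statistics
    box: dict = field(default_factory=dict)  # method -> box_statistics
    runs: dict = field(default_factory=dict)  # method -> fixture -> run record
    energy_comparison: dict = field(default_factory=dict)  # fixture -> diffs
    reference_method: str = "r-gdiis"

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "methods": self.methods,
                    "fixtures": self.fixtures,
                    "reference_method": self.reference_method,
                    "statistics": self.statistics,
                    "box": self.box,
                    "runs": self.runs,
                    "energy_comparison": self.energy_comparison,
                },
                fh,
                indent=2,
                default=float,
            )

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "method\tmean\tsd\tn_over_120\tn_not_converged\t"
                "q1\tmedian\tq3\twhisker_lo\twhisker_hi\n"
            )
            for m in self.methods:
                s, b = self.statistics[m], self.box[m]
                fh.write(
                    f"{m}\t{s['mean']:.2f}\t{s['sd']:.2f}\t{s['n_over_120']}\t"
                    f"{s['n_not_converged']}\t{b['q1']:.1f}\t{b['median']:.1f}\t"
                    f"{b['q3']:.1f}\t{b['whisker_lo']:.1f}\t{b['whisker_hi']:.1f}\n"
                )


def benchmark(
    fixture_names,
    methods=METHODS,
    config: RunConfig | None = None,
    reference_method: str | None = None,
    out_dir: str | None = None,
) -> BenchmarkSummary:
    """Run every method on every fixture and summarize iteration statistics."""
    fixture_names = list(fixture_names)
    methods = list(methods)
    if not fixture_names or not methods:
        raise ValueError("need at least one fixture and one method")
    base = config or RunConfig()
    reference = reference_method or (methods[0])
    summary = BenchmarkSummary(methods=methods, fixtures=fixture_names,
                               reference_method=reference)

    traces: dict[str, dict[str, IterationTrace]] = {m: {} for m in methods}
    for m in methods:
        cfg = RunConfig(**{**base.to_dict(), "method": m})
        for name in fixture_names:
            tr = optimize(make_fixture(name), cfg)
            traces[m][name] = tr
            summary.runs.setdefault(m, {})[name] = {
                "converged": tr.converged,
                "post_startup_iterations": tr.post_startup_count,
                "total_iterations": tr.total_iterations,
                "final_energy": tr.final_energy,
            }
        counts = [traces[m][n].post_startup_count for n in fixture_names]
        conv = [traces[m][n].converged for n in fixture_names]
        summary.statistics[m] = count_statistics(counts, conv)
        summary.box[m] = box_statistics([c for c, ok in zip(counts, conv) if ok] or counts)

    for name in fixture_names:
        energies = {m: traces[m][name].final_energy for m in methods
                    if traces[m][name].converged}
        if reference in energies and len(energies) > 1:
            summary.energy_comparison[name] = energy_differences(energies, reference)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        summary.to_json(os.path.join(out_dir, "benchmark.json"))
        summary.to_tsv(os.path.join(out_dir, "benchmark.tsv"))
    return summary
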