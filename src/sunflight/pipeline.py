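"""End-to-end analysis: QC -> per-flight summaries -> filter -> inference.

Reproduces the structure of the behavioural comparison: per group, flight
and fly counts through each stage, mean vector strength over all
QC-passing flights, mean absolute heading and a fly-level bootstrap CI of
the circular mean over directionally consistent flights (vector strength
strictly above threshold), plus pairwise fly-level permutation tests for
both statistics.  Stripe flights run through the identical machinery via
``flight_type='stripe'``; they never enter sun comparisons.

Every number in the report is regenerable from the cohort, the thresholds
and the seed recorded in the report: per-test and per-group sub-seeds are
spawned deterministically from the master seed.
"""
from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .inference import (
    DEFAULT_N_BOOT,
    DEFAULT_N_PERM,
    BootstrapCI,
    bootstrap_circular_ci,
    permutation_test,
)
from .io import (
    DEFAULT_COMPLETENESS_FRACTION,
    DEFAULT_VS_THRESHOLD,
    TRIAL_DURATION_S,
    Cohort,
    QCReport,
    apply_qc,
    select_heading_flights,
    summarize_cohort,
)


@dataclass
class GroupReport:
    label: str
    n_flies_in: int
    n_flights_in: int
    n_flies_qc: int
    n_flights_qc: int
    n_flies_heading: int
    n_flights_heading: int
    mean_vector_strength: float
    mean_abs_heading: float
    circ_mean_heading: float
    ci: BootstrapCI | None


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    statistic: str
    observed: float
    p_value: float
    n_perm: int
    seed: int


@dataclass
class AnalysisReport:
    flight_type: str
    groups: list
    tests: list
    qc: QCReport
    vs_threshold: float
    completeness_fraction: float
    n_perm: int
    n_boot: int
    seed: int
    log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "flight_type": self.flight_type,
            "seed": self.seed,
            "vs_threshold": self.vs_threshold,
            "completeness_fraction": self.completeness_fraction,
            "n_perm": self.n_perm,
            "n_boot": self.n_boot,
            "groups": [
                {
                    "label": g.label,
                    "n_flies_in": g.n_flies_in,
                    "n_flights_in": g.n_flights_in,
                    "n_flies_qc": g.n_flies_qc,
                    "n_flights_qc": g.n_flights_qc,
                    "n_flies_heading": g.n_flies_heading,
                    "n_flights_heading": g.n_flights_heading,
                    "mean_vector_strength": g.mean_vector_strength,
                    "mean_abs_heading": g.mean_abs_heading,
                    "circ_mean_heading": g.circ_mean_heading,
                    "ci_low": g.ci.ci_low if g.ci else None,
                    "ci_high": g.ci.ci_high if g.ci else None,
                    "ci_seed": g.ci.seed if g.ci else None,
                }
                for g in self.groups
            ],
            "tests": [
                {
                    "group_a": t.group_a,
                    "group_b": t.group_b,
                    "statistic": t.statistic,
                    "observed": t.observed,
                    "p_value": t.p_value,
                    "n_perm": t.n_perm,
                    "seed": t.seed,
                }
                for t in self.tests
            ],
            "log": self.log,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"# navigation analysis ({self.flight_type} flights)",
            f"seed={self.seed} vs_threshold={self.vs_threshold} "
            f"n_perm={self.n_perm} n_boot={self.n_boot}",
            "",
            "group\tflies_qc\tflights_qc\tflights_vs\tmean_vs"
            "\tmean_abs_heading\tcirc_mean\tci95",
        ]
        for g in self.groups:
            ci = f"[{g.ci.ci_low:.1f}, {g.ci.ci_high:.1f}]" if g.ci else "NA"
            lines.append(
                f"{g.label}\t{g.n_flies_qc}\t{g.n_flights_qc}"
                f"\t{g.n_flights_heading}\t{g.mean_vector_strength:.3f}"
                f"\t{g.mean_abs_heading:.1f}\t{g.circ_mean_heading:.1f}\t{ci}"
            )
        lines.append("")
        lines.append("group_a\tgroup_b\tstatistic\tobserved\tp_value")
        for t in self.tests:
            lines.append(
                f"{t.group_a}\t{t.group_b}\t{t.statistic}"
                f"\t{t.observed:.4f}\t{t.p_value:.4f}"
            )
        return "\n".join(lines) + "\n"


def _subseed(master: int, *key) -> int:
    """Deterministic 31-bit sub-seed for one test or CI (stable across runs)."""
    parts = [zlib.crc32(str(k).encode()) for k in key]
    ss = np.random.SeedSequence([int(master)] + parts)
    return int(ss.generate_state(1)[0] % (2**31))


def run_navigation_analysis(
    cohort: Cohort,
    seed: int,
    flight_type: str = "sun",
    vs_threshold: float = DEFAULT_VS_THRESHOLD,
    completeness_fraction: float = DEFAULT_COMPLETENESS_FRACTION,
    trial_duration_s: float = TRIAL_DURATION_S,
    n_perm: int = DEFAULT_N_PERM,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
) -> AnalysisReport:
    """Run the full QC -> summarise -> filter -> test pipeline.

    Vector-strength comparisons use all QC-passing flights of
    ``flight_type``; absolute-heading comparisons and per-group bootstrap
    CIs use only flights with vector strength strictly above
    ``vs_threshold``.  Raises if the cohort is empty or if any stage
    empties a group needed for a pairwise test.
    """
    if cohort.n_flights == 0:
        raise ValueError("no flights in cohort")
    log = []
    counts_in = {
        label: (len(flies), sum(len(f.flights) for f in flies))
        for label, flies in cohort.groups.items()
    }
    qc_cohort, qc_report = apply_qc(
        cohort,
        completeness_fraction=completeness_fraction,
        trial_duration_s=trial_duration_s,
    )
    log.append(
        f"qc: {qc_report.flights_in} flights in, {qc_report.flights_out} out "
        f"(stop rule {qc_report.discarded_stop_rule}, "
        f"incomplete {qc_report.discarded_incomplete})"
    )
    empty = [g for g in counts_in if g not in qc_cohort.groups]
    if empty:
        raise ValueError(f"QC emptied group(s) {empty} (stage: apply_qc)")

    summaries = summarize_cohort(qc_cohort, flight_type=flight_type)
    by_group: dict = {}
    for s in summaries:
        by_group.setdefault(s.group, []).append(s)
    empty = [g for g in qc_cohort.groups if g not in by_group]
    if empty:
        raise ValueError(
            f"no {flight_type} flights in group(s) {empty} (stage: summarize)"
        )
    log.append(f"summarize: {len(summaries)} {flight_type} flights")

    heading_by_group = {
        g: select_heading_flights(ss, vs_threshold) for g, ss in by_group.items()
    }
    log.append(
        "vs filter (> %.2f): %s"
        % (
            vs_threshold,
            {g: len(ss) for g, ss in heading_by_group.items()},
        )
    )

    groups_out = []
    for label in sorted(by_group):
        ss = by_group[label]
        hh = heading_by_group[label]
        mean_vs = float(np.mean([s.vector_strength for s in ss]))
        if hh:
            mean_abs = float(np.mean([s.abs_mean_heading for s in hh]))
            ci = bootstrap_circular_ci(
                hh,
                n_boot=n_boot,
                seed=_subseed(seed, "ci", flight_type, label),
                level=level,
            )
            circ_mean = ci.mean_heading
        else:
            mean_abs, ci, circ_mean = math.nan, None, math.nan
        groups_out.append(
            GroupReport(
                label=label,
                n_flies_in=counts_in.get(label, (0, 0))[0],
                n_flights_in=counts_in.get(label, (0, 0))[1],
                n_flies_qc=len(qc_cohort.groups.get(label, [])),
                n_flights_qc=len(ss),
                n_flies_heading=len({s.fly_id for s in hh}),
                n_flights_heading=len(hh),
                mean_vector_strength=mean_vs,
                mean_abs_heading=mean_abs,
                circ_mean_heading=circ_mean,
                ci=ci,
            )
        )

    tests = []
    for a, b in combinations(sorted(by_group), 2):
        s = _subseed(seed, "perm", flight_type, "vs", a, b)
        res = permutation_test(
            by_group[a], by_group[b], "vector_strength_mean_diff", n_perm, s
        )
        tests.append(
            PairwiseTest(a, b, res.statistic_name, res.observed_stat, res.p_value, n_perm, s)
        )
        if not heading_by_group[a] or not heading_by_group[b]:
            raise ValueError(
                f"vector-strength filter emptied group "
                f"{a if not heading_by_group[a] else b} (stage: select_heading_flights)"
            )
        s = _subseed(seed, "perm", flight_type, "heading", a, b)
        res = permutation_test(
            heading_by_group[a], heading_by_group[b], "abs_heading_mean_diff", n_perm, s
        )
        tests.append(
            PairwiseTest(a, b, res.statistic_name, res.observed_stat, res.p_value, n_perm, s)
        )
    log.append(f"tests: {len(tests)} pairwise comparisons")

    return AnalysisReport(
        flight_type=flight_type,
        groups=groups_out,
        tests=tests,
        qc=qc_report,
        vs_threshold=vs_threshold,
        completeness_fraction=completeness_fraction,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
        log=log,
    )
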