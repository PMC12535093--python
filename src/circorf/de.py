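"""Junction-read quantification and differential screening.

Expression of a circRNA is measured as junction reads per million total
mapped reads (RPM).  Differential expression between vehicle and treated
groups is assessed with a conditional exact binomial rate test on pooled
junction-read counts: given the two groups' total library sizes LA and LB,
under the null of equal per-read rates the pooled count kA of group A is
binomial(kA+kB, LA/(LA+LB)).  This is a defined, dependency-free substitute
for a negative-binomial GLM fit, not a reproduction of one.  Calls use raw
p < alpha and |log2FC| > min_abs_lfc; a circle is "sustained down" when it
is called down at both timepoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DifferentialResult",
    "JunctionCountMatrix",
    "ddct",
    "de_filter",
    "differential_table",
    "rate_test",
    "rpm",
    "sustained_down",
]


@dataclass
class JunctionCountMatrix:
    """circRNA × sample junction-read counts with sample metadata.

    ``counts`` is an integer DataFrame (rows circ_id, columns sample_id);
    ``library_sizes``, ``conditions`` and ``timepoints`` are Series indexed
    by sample_id.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    conditions: pd.Series
    timepoints: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.counts.columns)
        for name, s in (
            ("library_sizes", self.library_sizes),
            ("conditions", self.conditions),
            ("timepoints", self.timepoints),
        ):
            missing = set(samples) - set(s.index)
            if missing:
                raise ValueError(f"{name} missing samples: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.library_sizes[samples] <= 0).any():
            raise ValueError("library sizes must be > 0")

    @property
    def circ_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    def samples_for(self, condition: str, timepoint: str) -> list:
        return [
            s
            for s in self.sample_ids
            if self.conditions[s] == condition and self.timepoints[s] == timepoint
        ]

    def rpm_matrix(self) -> pd.DataFrame:
        """Per-sample RPM for every circRNA."""
        return self.counts / self.library_sizes[self.sample_ids] * 1e6


def rpm(junction_reads: int, total_mapped: int) -> float:
    """Reads per million: junction_reads / total_mapped × 10⁶."""
    if total_mapped <= 0:
        raise ValueError(f"total_mapped must be > 0, got {total_mapped}")
    if junction_reads < 0:
        raise ValueError(f"junction_reads must be >= 0, got {junction_reads}")
    return junction_reads / total_mapped * 1e6


def rate_test(counts_A, counts_B, lib_A, lib_B) -> tuple:
    """Exact two-group rate comparison on pooled junction counts.

    Returns ``(log2fc, p_value)`` with group A = vehicle, B = treated;
    positive fold change means higher in treated.  The two-sided p doubles
    the smaller binomial tail and is capped at 1.  Fold changes use a 0.5
    pseudocount per pooled group.  Both groups all-zero is the defined
    degenerate case (0, 1).
    """
    kA, kB = int(np.sum(counts_A)), int(np.sum(counts_B))
    LA, LB = float(np.sum(lib_A)), float(np.sum(lib_B))
    if len(np.atleast_1d(counts_A)) < 1 or len(np.atleast_1d(counts_B)) < 1:
        raise ValueError("each group needs at least one sample")
    if LA <= 0 or LB <= 0:
        raise ValueError("library sizes must be > 0")
    log2fc = math.log2(((kB + 0.5) / LB) / ((kA + 0.5) / LA))
    n = kA + kB
    if n == 0:
        return 0.0, 1.0
    p_null = LA / (LA + LB)
    lower = stats.binom.cdf(kA, n, p_null)
    upper = stats.binom.sf(kA - 1, n, p_null)
    p = min(1.0, 2.0 * min(lower, upper))
    return log2fc, float(p)


def de_filter(log2fc: float, p_value: float, alpha: float = 0.05, min_abs_lfc: float = 1.0) -> str:
    """Directional call: 'down', 'up' or 'none' under p < alpha and
    |log2FC| > min_abs_lfc."""
    if alpha <= 0 or min_abs_lfc <= 0:
        raise ValueError("thresholds must be > 0")
    if p_value < alpha and log2fc < -min_abs_lfc:
        return "down"
    if p_value < alpha and log2fc > min_abs_lfc:
        return "up"
    return "none"


def sustained_down(call_d10: str | None, call_d20: str | None) -> bool:
    """True iff the circle is called down at both timepoints."""
    if call_d10 is None or call_d20 is None:
        raise ValueError("both timepoints required for the sustained-suppression flag")
    return call_d10 == "down" and call_d20 == "down"


def ddct(ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control) -> float:
    """Relative expression 2^−ΔΔCt for qPCR validation."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct_val = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct_val)


@dataclass
class DifferentialResult:
    """Per-circRNA differential outcome across timepoints."""

    circ_id: str
    log2fc: dict = field(default_factory=dict)   # timepoint -> log2fc
    p_value: dict = field(default_factory=dict)  # timepoint -> p
    call: dict = field(default_factory=dict)     # timepoint -> up/down/none
    sustained_down: bool = False


def differential_table(
    matrix: JunctionCountMatrix,
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
    vehicle: str = "vehicle",
    treated: str = "treated",
) -> tuple:
    """Run the rate test for every circRNA at every timepoint.

    Returns ``(table, results)``: a tidy DataFrame (circ_id, timepoint, kA,
    kB, log2fc, p, p_bh, call, sustained_down) and a dict circ_id →
    :class:`DifferentialResult`.  The Benjamini–Hochberg column is reported
    for reference only; calls use raw p-values.
    """
    timepoints = sorted(set(matrix.timepoints[matrix.sample_ids]))
    rows = []
    for tp in timepoints:
        sA = matrix.samples_for(vehicle, tp)
        sB = matrix.samples_for(treated, tp)
        if not sA or not sB:
            raise ValueError(f"timepoint {tp}: missing {vehicle} or {treated} samples")
        libA = matrix.library_sizes[sA].to_numpy()
        libB = matrix.library_sizes[sB].to_numpy()
        for cid in matrix.circ_ids:
            cA = matrix.counts.loc[cid, sA].to_numpy()
            cB = matrix.counts.loc[cid, sB].to_numpy()
            lfc, p = rate_test(cA, cB, libA, libB)
            rows.append(
                {
                    "circ_id": cid,
                    "timepoint": tp,
                    "kA": int(cA.sum()),
                    "kB": int(cB.sum()),
                    "log2fc": lfc,
                    "p": p,
                    "call": de_filter(lfc, p, alpha, min_abs_lfc),
                }
            )
    table = pd.DataFrame(rows)
    table["p_bh"] = stats.false_discovery_control(table["p"], method="bh")

    results = {}
    for cid, sub in table.groupby("circ_id", sort=True):
        res = DifferentialResult(circ_id=cid)
        for _, r in sub.iterrows():
            res.log2fc[r["timepoint"]] = r["log2fc"]
            res.p_value[r["timepoint"]] = r["p"]
            res.call[r["timepoint"]] = r["call"]
        if len(timepoints) >= 2:
            res.sustained_down = all(res.call[tp] == "down" for tp in timepoints)
        results[cid] = res
    table["sustained_down"] = table["circ_id"].map(
        lambda c: results[c].sustained_down
    )
    return table, results
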