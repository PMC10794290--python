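"""Benchmarking a call set against a truth list of known variants.

Matching is by (chrom, pos, alt) when the truth provides alternative
alleles; position-only matching is available as an explicit relaxation.
Precision = TP/(TP+FP) and sensitivity = TP/(TP+FN); a zero denominator
yields None (undefined), never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")


def confusion_counts(calls: Iterable[Hashable], truth: Iterable[Hashable],
                     assayed: Iterable[Hashable] | None = None) -> ConfusionCounts:
    """TP/FP/FN from set comparison of call keys against truth keys.

    Keys are any hashable site identifiers — typically (chrom, pos, alt)
    tuples.  When ``assayed`` is given, truth is first restricted to assayed
    sites so that unassayable variants do not count as misses.
    """
    calls = set(calls)
    truth = set(truth)
    if assayed is not None:
        assayed = set(assayed)
        truth = truth & assayed
    tp = len(calls & truth)
    return ConfusionCounts(TP=tp, FP=len(calls - truth), FN=len(truth - calls))


def precision_sensitivity(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """(Prec, Sens) = (TP/(TP+FP), TP/(TP+FN)); None where undefined."""
    prec = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    return prec, sens


def truth_keys_from_table(truth: pd.DataFrame, match_alt: bool = True) -> set:
    """Site keys for the mutant rows of a simulator truth table (or any
    table with chrom/pos/alt and an is_mutant or alt != '.' convention)."""
    if "is_mutant" in truth.columns:
        rows = truth[truth["is_mutant"]]
    else:
        rows = truth[truth["alt"] != "."]
    if match_alt:
        return {(r.chrom, int(r.pos), r.alt) for r in rows.itertuples()}
    return {(r.chrom, int(r.pos)) for r in rows.itertuples()}


def call_keys(calls, match_alt: bool = True) -> set:
    """Site keys from CallRecord-like objects (chrom/pos/alt fields)."""
    if match_alt:
        return {(c.chrom, int(c.pos), c.alt) for c in calls}
    return {(c.chrom, int(c.pos)) for c in calls}


def evaluation_report(calls, truth_keys: set, assayed_keys: set | None = None,
                      match_alt: bool = True) -> dict:
    """One-stop TSV-friendly report dict: TP, FP, FN, Prec, Sens."""
    keys = call_keys(calls, match_alt=match_alt)
    c = confusion_counts(keys, truth_keys, assayed_keys)
    prec, sens = precision_sensitivity(c)
    return {"TP": c.TP, "FP": c.FP, "FN": c.FN, "Prec": prec, "Sens": sens}
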