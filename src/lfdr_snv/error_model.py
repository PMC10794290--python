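"""Per-site sequencing-error rates from Phred-scaled quality scores.

Each allele class U in {R, M, X1, X2} carries a mean base-call quality
BQ^U and a mean mapping quality MQ^U (Phred units).  The class quality is
their average, Q^U = (BQ^U + MQ^U)/2; the site quality Q is the read-count
weighted mean of the class qualities; and the per-read error probability is
e = 10^(-Q/10), clamped away from 0 and 1.

A Phred quality of 20 therefore corresponds to e = 0.01 — one miscalled
base per hundred read observations — which is also the recommended global
rate when quality-derived per-site rates are switched off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

#: Lower clamp: keeps log(e/3) finite in the likelihoods.
E_MIN = 1e-10
#: Upper clamp: above 3/4 the three wrong alleles would jointly be likelier
#: than the true one, which no read model should assert.
E_MAX = 0.75
#: Recommended global per-read error rate (Phred 20).
GLOBAL_ERROR_RATE = 0.01


@dataclass(frozen=True)
class SiteQuality:
    """Quality summary for one site.

    ``q_by_class`` maps class labels (R/M/X1/X2) to Q^U = (BQ^U+MQ^U)/2 for
    classes with nonzero count; ``q`` is the count-weighted site quality and
    ``e`` the clamped error probability 10^(-q/10).  ``mean_bq``/``mean_mq``
    are the count-weighted per-site means used by the pre-filters.
    """

    q_by_class: Mapping[str, float]
    q: float
    e: float
    mean_bq: float
    mean_mq: float


def allele_mean_quality(bq: float, mq: float) -> float:
    """Average of base-call and mapping quality, Q^U = (BQ^U + MQ^U)/2."""
    if bq < 0 or mq < 0:
        raise ValueError(f"Phred qualities must be >= 0, got bq={bq}, mq={mq}")
    return (bq + mq) / 2.0


def site_weighted_quality(counts, q_by_class: Mapping[str, float] | None = None) -> float:
    """Count-weighted mean quality Q = (Q^R R + Q^M M + Q^X1 X1 + Q^X2 X2)/K.

    ``counts`` is a :class:`~lfdr_snv.counts_io.SiteCounts`; ``q_by_class``
    maps the labels "R","M","X1","X2" to class qualities.  Classes with zero
    count contribute nothing regardless of their (possibly undefined)
    quality value.
    """
    weights = {"R": counts.R, "M": counts.M, "X1": counts.X1, "X2": counts.X2}
    k = sum(weights.values())
    if k == 0:
        raise ValueError(f"no reads at {counts.chrom}:{counts.pos}: quality undefined")
    q_by_class = q_by_class or {}
    total = 0.0
    for label, w in weights.items():
        if w == 0:
            continue
        q = q_by_class.get(label)
        if q is None:
            raise ValueError(f"class {label} has {w} reads but no quality value")
        total += q * w
    return total / k


def error_rate_from_quality(q: float, e_min: float = E_MIN, e_max: float = E_MAX) -> float:
    """Error probability e = 10^(-Q/10), clamped to [e_min, e_max]."""
    if q < 0:
        raise ValueError(f"Phred quality must be >= 0, got {q}")
    if not (0.0 < e_min < e_max < 1.0):
        raise ValueError(f"require 0 < e_min < e_max < 1, got ({e_min}, {e_max})")
    e = 10.0 ** (-q / 10.0)
    return float(np.clip(e, e_min, e_max))


def phred_from_error_rate(e: float) -> float:
    """Inverse map Q = -10 log10(e), used by the simulator to emit qualities."""
    if not (0.0 < e <= 1.0):
        raise ValueError(f"error rate must be in (0, 1], got {e}")
    return -10.0 * np.log10(e)
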