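"""Cohort bookkeeping helpers.

Small arithmetic utilities for accounting of recruitment, attrition and
conversion in a longitudinal cohort, plus the onset-date midpoint
convention used when a diagnosis is established between two visits.
"""

from __future__ import annotations

__all__ = ["conversion_percentage", "retained_for_followup", "onset_midpoint"]


def conversion_percentage(n_converters: int, n_total: int, ndigits: int = 1) -> float:
    """Percentage of a cohort that converted, rounded to ``ndigits``."""
    if n_total <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= n_converters <= n_total:
        raise ValueError("converter count must lie in [0, n_total]")
    return round(100.0 * n_converters / n_total, ndigits)


def retained_for_followup(n_recruited: int, attrition_counts) -> int:
    """Participants retained for repeat assessment after per-reason attrition."""
    lost = sum(int(c) for c in attrition_counts)
    if any(int(c) < 0 for c in attrition_counts):
        raise ValueError("attrition counts must be non-negative")
    retained = int(n_recruited) - lost
    if retained < 0:
        raise ValueError("attrition exceeds the recruited total")
    return retained


def onset_midpoint(previous_visit: float, diagnosis_visit: float) -> float:
    """Onset date convention: midpoint between the visit at which a diagnosis
    was established and the previous attended visit."""
    if diagnosis_visit <= previous_visit:
        raise ValueError("diagnosis visit must follow the previous visit")
    return 0.5 * (previous_visit + diagnosis_visit)
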