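"""Small statistics helpers for cohort reporting."""

from __future__ import annotations

from scipy import stats as sstats


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 12,
                         digits: int | None = 4) -> float:
    """Family-wise corrected per-test p threshold, alpha / n_tests.

    For the 12 feature comparisons at alpha = 0.05 this is 0.0042 when
    rounded to four decimals (the precision used in reporting).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    thr = alpha / n_tests
    return round(thr, digits) if digits is not None else thr


def binomial_above_chance_p(n_correct: int, n_total: int,
                            chance: float = 0.5) -> float:
    """One-sided binomial p-value that accuracy exceeds chance."""
    return float(sstats.binomtest(n_correct, n_total, chance,
                                  alternative="greater").pvalue)
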