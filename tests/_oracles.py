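"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation path (and scipy's peak
machinery): quadratic-time, definition-level computations.
"""

import numpy as np


def prominence_of(prof: np.ndarray, i: int) -> float:
    """Topographic prominence of the local maximum at index ``i``.

    Walk outward from the peak in each direction until a strictly
    higher sample (or the signal border) is met, recording the lowest
    level crossed; the prominence is the peak height above the higher
    of the two lowest levels.
    """
    h = prof[i]
    left_min = h
    j = i - 1
    while j >= 0 and prof[j] <= h:
        left_min = min(left_min, prof[j])
        j -= 1
    right_min = h
    j = i + 1
    while j < len(prof) and prof[j] <= h:
        right_min = min(right_min, prof[j])
        j += 1
    return h - max(left_min, right_min)


def brute_force_peak_count(prof: np.ndarray, min_prominence: float) -> int:
    """O(n^2) peak count: strict local maxima with sufficient prominence.

    Endpoints are never peaks.  (Profiles with exact ties/plateaus are
    outside this oracle's scope; the random test profiles have none.)
    """
    prof = np.asarray(prof, dtype=float)
    count = 0
    for i in range(1, len(prof) - 1):
        if prof[i] > prof[i - 1] and prof[i] > prof[i + 1]:
            if prominence_of(prof, i) >= min_prominence:
                count += 1
    return count
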