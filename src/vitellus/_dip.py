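"""Core routine for Hartigan's dip statistic.

The dip of an empirical distribution function :math:`F_n` is the smallest
sup-norm distance between :math:`F_n` and the class of unimodal distribution
functions (CDFs that are convex up to a mode and concave after it).  It is
computed here by the classical iteration that repeatedly fits the greatest
convex minorant (GCM) and least concave majorant (LCM) of the ECDF on a
shrinking candidate modal interval, accumulating the largest one-sided
deviation found outside the modal interval.  The final dip is half that
largest deviation.

All arithmetic inside the iteration is carried out in *count* units
(0..n), which keeps the hull bookkeeping in mostly-integer quantities; the
statistic is scaled by 1/(2n) at the end.

The hot loop is JIT-compiled with numba because the Monte-Carlo calibration
of the test statistic evaluates the dip on hundreds of null samples.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def _dip_sorted(x):  # pragma: no cover - exercised via dip_statistic
    """Dip statistic of a sorted 1-D sample ``x`` (n >= 2)."""
    n = x.shape[0]
    if x[n - 1] == x[0]:
        return 0.0

    low = 0
    high = n - 1
    big_d = 0.0  # best deviation so far, in count units (twice n*dip)

    gcm = np.empty(n, np.int64)
    lcm = np.empty(n, np.int64)
    gval = np.empty(n, np.float64)
    lval = np.empty(n, np.float64)
    gvert = np.empty(n, np.uint8)
    lvert = np.empty(n, np.uint8)

    while True:
        if low >= high or x[high] == x[low]:
            break

        # Greatest convex minorant of the points (x[i], i) on [low, high].
        # The y-value i is the left-limit count of the ECDF at x[i].
        ng = 0
        for i in range(low, high + 1):
            while ng >= 2:
                i1 = gcm[ng - 1]
                i0 = gcm[ng - 2]
                # remove i1 when it lies on or above the chord i0 -> i
                cross = (i1 - i0) * (x[i] - x[i0]) - (i - i0) * (x[i1] - x[i0])
                if cross >= 0.0:
                    ng -= 1
                else:
                    break
            gcm[ng] = i
            ng += 1

        # Least concave majorant of the points (x[i], i + 1); the y-value is
        # the right-limit count of the ECDF at x[i].
        nl = 0
        for i in range(low, high + 1):
            while nl >= 2:
                i1 = lcm[nl - 1]
                i0 = lcm[nl - 2]
                cross = (i1 - i0) * (x[i] - x[i0]) - (i - i0) * (x[i1] - x[i0])
                if cross <= 0.0:
                    nl -= 1
                else:
                    break
            lcm[nl] = i
            nl += 1

        # Evaluate both hulls at every index in [low, high]; vertical hull
        # segments (tied observations) take the minorant's lower / the
        # majorant's upper count and are flagged, because deviations of the
        # ECDF across an atom must not be charged against a curve that is
        # free to jump there.
        sg = 0
        sl = 0
        for i in range(low, high + 1):
            while sg < ng - 1 and gcm[sg + 1] < i:
                sg += 1
            a = gcm[sg]
            b = gcm[min(sg + 1, ng - 1)]
            if b == a or x[b] == x[a]:
                gval[i - low] = float(a)
                gvert[i - low] = 1
            else:
                gval[i - low] = a + (b - a) * (x[i] - x[a]) / (x[b] - x[a])
                gvert[i - low] = 0
            while sl < nl - 1 and lcm[sl + 1] < i:
                sl += 1
            a = lcm[sl]
            b = lcm[min(sl + 1, nl - 1)]
            if b == a or x[b] == x[a]:
                lval[i - low] = float(b + 1)
                lvert[i - low] = 1
            else:
                lval[i - low] = (a + 1) + (b - a) * (x[i] - x[a]) / (x[b] - x[a])
                lvert[i - low] = 0

        # Largest gap between the two hulls.  Both curves are linear in x
        # between hull contact points, so the maximum occurs at a contact
        # point of one of them; evaluating only there keeps the recursion
        # exact under floating-point ties.
        d = -1.0
        istar = low
        for j in range(ng):
            i = gcm[j]
            gap = lval[i - low] - gval[i - low]
            if gap > d:
                d = gap
                istar = i
        for j in range(nl):
            i = lcm[j]
            gap = lval[i - low] - gval[i - low]
            if gap > d:
                d = gap
                istar = i

        if d <= big_d + 1e-12:
            break

        # New modal interval brackets the largest gap with the nearest hull
        # contact points on either side.
        new_low = low
        for j in range(ng):
            if gcm[j] <= istar:
                new_low = gcm[j]
            else:
                break
        new_high = high
        for j in range(nl - 1, -1, -1):
            if lcm[j] >= istar:
                new_high = lcm[j]
            else:
                break

        # Deviations of the ECDF outside the new modal interval: above the
        # convex minorant on the left flank, below the concave majorant on
        # the right flank.  A non-degenerate flank always contributes at
        # least one count (the deviation at a hull contact point); indices
        # sitting on vertical hull segments contribute only that floor.
        dl = 1.0 if new_low > low else 0.0
        for i in range(low, new_low + 1):
            if gvert[i - low]:
                continue
            dev = (i + 1) - gval[i - low]
            if dev > dl:
                dl = dev
        du = 1.0 if high > new_high else 0.0
        for i in range(new_high, high + 1):
            if lvert[i - low]:
                continue
            dev = lval[i - low] - i
            if dev > du:
                du = dev

        if dl > big_d:
            big_d = dl
        if du > big_d:
            big_d = du

        if new_low == low and new_high == high:
            break
        low = new_low
        high = new_high

    return big_d / (2.0 * n)


def dip_from_sorted(x: np.ndarray) -> float:
    """Dip statistic of an already-sorted float64 sample."""
    return float(_dip_sorted(np.ascontiguousarray(x, dtype=np.float64)))
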