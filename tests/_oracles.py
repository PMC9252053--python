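"""Independent reference implementations used to validate the production
code paths. Both classifiers below transcribe the read-classification
contract directly — enumerate every ungapped alignment offset of the
read (and its reverse complement) against every junction window and
apply the matched-bases / mismatch-rate rules — without sharing any
code with the package's vectorised engine.
"""

from functools import lru_cache

import numpy as np

from petalotype._seq import revcomp, seq_to_array


@lru_cache(maxsize=8192)
def _arr(s: str) -> np.ndarray:
    return seq_to_array(s)

MIN_EXT = 5
TRUNC_MAX_MATCH = 0.5


def _offset_stats_python(read, window, flank, offset):
    """Matched-base counts at one offset, counted base by base."""
    left = right = aligned = 0
    for i, base in enumerate(read):
        w = offset + i
        if 0 <= w < len(window):
            aligned += 1
            if base == window[w]:
                if w < flank:
                    left += 1
                else:
                    right += 1
    return left, right, aligned


def _ext_spans(read_len, window_len, flank, offset):
    ls = max(0, offset)
    le = min(flank, offset + read_len)
    rs = max(flank, offset)
    re = min(window_len, offset + read_len)
    return max(0, le - ls), max(0, re - rs)


def _classify_with(stats_fn, read, js, min_overlap, rate):
    if len(read) < 2 * min_overlap:
        return "uninformative"
    f = js.flank

    def supported(window, seq):
        for off in range(-(len(seq) - 1), len(window)):
            l, r, a = stats_fn(seq, window, f, off)
            if l >= min_overlap and r >= min_overlap and (a - l - r) <= rate * a:
                return True
        return False

    def truncated(window, seq):
        for off in range(-(len(seq) - 1), len(window)):
            l, r, _ = stats_fn(seq, window, f, off)
            l_ext, r_ext = _ext_spans(len(seq), len(window), f, off)
            l_clean = l >= min_overlap and (l_ext - l) <= rate * l_ext
            r_clean = r >= min_overlap and (r_ext - r) <= rate * r_ext
            if l_clean and r_ext >= MIN_EXT and r < TRUNC_MAX_MATCH * r_ext:
                return True
            if r_clean and l_ext >= MIN_EXT and l < TRUNC_MAX_MATCH * l_ext:
                return True
        return False

    both = (read, revcomp(read))
    for w in js.variant_junctions:
        if any(supported(w, s) for s in both):
            return "variant"
    if any(supported(w, s) for w in js.wt_junctions for s in both):
        return "wt"
    if any(truncated(w, s) for w in js.wt_junctions for s in both):
        return "truncated"
    return "uninformative"


def bruteforce_classify(read, js, min_overlap=20, rate=0.05):
    """Pure-python exhaustive classifier (slow; small read counts)."""
    return _classify_with(_offset_stats_python, read, js, min_overlap, rate)


def _offset_stats_numpy(read, window, flank, offset):
    """Same counts, but each offset's comparison is one vectorised slice
    (still one explicit alignment per offset)."""
    r = _arr(read)
    w = _arr(window)
    lo = max(0, -offset)
    hi = min(len(r), len(w) - offset)
    if hi <= lo:
        return 0, 0, 0
    eq = r[lo:hi] == w[offset + lo : offset + hi]
    aligned = hi - lo
    boundary = flank - offset  # read index where the window centre falls
    split = int(np.clip(boundary, lo, hi)) - lo
    left = int(eq[:split].sum())
    right = int(eq[split:].sum())
    return left, right, aligned


def exhaustive_classify(read, js, min_overlap=20, rate=0.05):
    """Offset-by-offset exhaustive classifier with vectorised slice
    comparisons; fast enough for the 10,000-read comparison."""
    return _classify_with(_offset_stats_numpy, read, js, min_overlap, rate)
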