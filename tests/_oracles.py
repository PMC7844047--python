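"""Independent test oracles, deliberately implemented differently from the
package: a linear semi-global alignment against an explicit periodic
reference (vs. the package's phase-ring DP), and a brute-force consecutive
frame-copy scanner."""

from __future__ import annotations


def periodic_alignment_oracle(
    seq: str,
    motif: str,
    match: int = 2,
    mismatch: int = 5,
    indel: int = 17,
) -> int:
    """Best global alignment score of ``seq`` against any window of an
    infinite periodic extension of ``motif``.

    Implemented as semi-global Needleman-Wunsch versus a long explicit
    repeat of the motif: gaps at the reference ends are free (free start
    and end phase / repeat length), everything else is charged.
    """
    n = len(seq)
    if n == 0:
        return 0
    m = len(motif)
    reps = (3 * n + 2 * m) // m + 1
    ref = motif * reps
    L = len(ref)
    prev = [0] * (L + 1)  # free leading reference gap
    for i in range(1, n + 1):
        c = seq[i - 1]
        cur = [prev[0] - indel]
        for j in range(1, L + 1):
            diag = prev[j - 1] + (match if c == ref[j - 1] else -mismatch)
            up = prev[j] - indel
            left = cur[j - 1] - indel
            cur.append(max(diag, up, left))
        prev = cur
    return max(prev)  # free trailing reference gap


def exact_frame_runs(sequence: str, frames: set[str], min_units: int) -> list[tuple[int, int]]:
    """Maximal regions of >= min_units exact consecutive copies of any single
    frame, found by brute force."""
    runs = []
    for frame in frames:
        k = len(frame)
        i = 0
        while i + k * min_units <= len(sequence):
            count = 0
            while sequence[i + count * k : i + (count + 1) * k] == frame:
                count += 1
            if count >= min_units:
                runs.append((i, i + count * k))
                i += count * k
            else:
                i += 1
    # merge duplicates/containments from different frames of the same run
    runs.sort()
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
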