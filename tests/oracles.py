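"""Independent brute-force oracles used by the tests.

Everything here is written with plain scalar loops and must stay independent
of the package's vectorised implementation paths.
"""

import math


def naive_score(counts):
    total = 0.0
    for value in counts:
        total += math.log(1.0 + value)
    return total


def naive_profile(run_counts, global_counts, lam, a):
    """Pseudocount-smoothed profile via scalar loops."""
    T = len(run_counts)
    grand = 0.0
    for value in global_counts:
        grand += value
    if grand == 0:
        pbar = [1.0 / T] * T
    else:
        pbar = [value / grand for value in global_counts]
    weights = [run_counts[j] + lam * T * pbar[j] + a for j in range(T)]
    norm = sum(weights)
    return [w / norm for w in weights]


def naive_expected_score(global_counts, run_counts, b, q_hat, lam, a):
    profile = naive_profile(run_counts, global_counts, lam, a)
    bumped = [global_counts[j] + b * q_hat * profile[j] for j in range(len(global_counts))]
    return naive_score(bumped)


def naive_argmax_set(per_run_counts, global_counts, q_hats, b, lam, a, rel_tol=1e-12):
    """Set of run ids maximising the expected post-batch score (ties within
    rel_tol of the max)."""
    values = {
        run_id: naive_expected_score(global_counts, counts, b, q_hats[run_id], lam, a)
        for run_id, counts in per_run_counts.items()
    }
    v_max = max(values.values())
    tol = rel_tol * max(abs(v_max), 1.0)
    return {run_id for run_id, v in values.items() if v >= v_max - tol}, values


_REF_OPS = set("MDN=X")


def naive_introns(position, cigar, sequence):
    """Introns via explicit per-base reference walk: classify every consumed
    reference base as aligned or skipped, then take maximal skipped runs."""
    import re

    ops = re.findall(r"(\d+)([MIDNSHP=X])", cigar)
    skipped = []  # (ref_pos, is_skipped) for consumed bases
    ref = position
    for length_str, op in ops:
        length = int(length_str)
        if op in _REF_OPS:
            for _ in range(length):
                skipped.append((ref, op == "N"))
                ref += 1
    introns = []
    run_start = None
    prev = None
    for pos, is_skip in skipped + [(None, False)]:
        if is_skip and run_start is None:
            run_start = pos
        elif not is_skip and run_start is not None:
            introns.append((sequence, run_start, prev))
            run_start = None
        prev = pos
    return introns
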