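"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by a different route than the package:
position-set algebra for class codes, exhaustive (frame, start, stop)
enumeration for ORFs, a plain quadratic Smith-Waterman DP for alignment
identity, and a pH grid search for the isoelectric point.
"""

from __future__ import annotations

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_longest_orf(seq: str) -> tuple[int, int]:
    """Enumerate every (frame, ATG, stop) triple; longest wins, then
    smallest start."""
    best = (0, 0)
    n = len(seq)
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        length = None
        pos = start
        while pos + 3 <= n:
            if pos > start and seq[pos : pos + 3] in STOPS:
                length = pos + 3 - start
                break
            pos += 3
        if length is None:
            length = ((n - start) // 3) * 3
        if length > best[1] or (length == best[1] and start < best[0]):
            best = (start, length)
    return best


# --- class-code predicate checker (position sets) -------------------------


def _positions(exons):
    pos = set()
    for s, e in exons:
        pos.update(range(s, e))
    return pos


def _introns(exons):
    exons = sorted(exons)
    return [(a[1], b[0]) for a, b in zip(exons, exons[1:])]


def oracle_code_for_pair(q, r, run_on_distance=2000, single_frac=0.8):
    """q, r: (strand, [(start, end), ...]) on one chromosome."""
    qs, qe = q[0], sorted(q[1])
    rs, re_ = r[0], sorted(r[1])
    same = qs == rs
    qpos, rpos = _positions(qe), _positions(re_)
    qint, rint = _introns(qe), _introns(re_)
    q_span = (qe[0][0], qe[-1][1])
    r_span = (re_[0][0], re_[-1][1])
    q_span_pos = set(range(*q_span))
    r_span_pos = set(range(*r_span))

    if same:
        if qint and rint and tuple(qint) == tuple(rint):
            return "="
        if not qint and not rint:
            shared = len(q_span_pos & r_span_pos)
            if shared >= single_frac * len(q_span_pos) and shared >= single_frac * len(r_span_pos):
                return "="
        if qpos <= rpos and all(i in rint for i in qint):
            return "c"
        if rint:
            m = len(rint)
            for i in range(len(qint) - m + 1):
                if qint[i : i + m] == rint:
                    return "k"
        covers = q_span[0] <= r_span[0] and q_span[1] >= r_span[1]
        if covers and rint:
            retained = sum(1 for i in rint if set(range(*i)) <= qpos)
            if retained == len(rint):
                return "m"
            if retained >= 1:
                return "n"
        if set(qint) & set(rint):
            return "j"
        if not qint and qpos & rpos and any(qpos & set(range(*i)) for i in rint):
            return "e"
        if qpos & rpos:
            return "o"
    else:
        if set(qint) & set(rint):
            return "s"
        if qpos & rpos:
            return "x"
    if any(q_span_pos <= set(range(*i)) for i in rint):
        return "i"
    if any(r_span_pos <= set(range(*i)) for i in qint):
        return "y"
    if same and not (q_span_pos & r_span_pos):
        if q_span[0] >= r_span[1]:
            gap = q_span[0] - r_span[1]
        else:
            gap = r_span[0] - q_span[1]
        if gap <= run_on_distance:
            return "p"
    return "u"


PRIORITY = "=ckmnjeosxiypu"


def oracle_best_code(query, refs, run_on_distance=2000, single_frac=0.8):
    """refs: list of (ref_id, (strand, exons)); returns (code, ref_id)."""
    best = None
    q_span = (sorted(query[1])[0][0], sorted(query[1])[-1][1])
    for rid, r in refs:
        code = oracle_code_for_pair(query, r, run_on_distance, single_frac)
        if code == "u":
            continue
        r_span = (sorted(r[1])[0][0], sorted(r[1])[-1][1])
        if q_span[0] >= r_span[1]:
            dist = q_span[0] - r_span[1]
        elif r_span[0] >= q_span[1]:
            dist = r_span[0] - q_span[1]
        else:
            dist = 0
        key = (PRIORITY.index(code), dist, rid, code)
        if best is None or key < best:
            best = key
    return ("u", None) if best is None else (best[3], best[2])


# --- Smith-Waterman DP -----------------------------------------------------


def smith_waterman(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Plain quadratic local-alignment DP with traceback.

    Returns (score, identity_percent, alignment_columns).
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    ptr = [[0] * (m + 1) for _ in range(n + 1)]  # 0 stop, 1 diag, 2 up, 3 left
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        Hi, Hi1, pi = H[i], H[i - 1], ptr[i]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = Hi1[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = Hi1[j] + gap
            left = Hi[j - 1] + gap
            v = diag
            p = 1
            if up > v:
                v, p = up, 2
            if left > v:
                v, p = left, 3
            if v <= 0:
                v, p = 0.0, 0
            Hi[j], pi[j] = v, p
            if v > best:
                best, bi, bj = v, i, j
    if best <= 0:
        return 0.0, 0.0, 0
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and ptr[i][j] != 0:
        p = ptr[i][j]
        columns += 1
        if p == 1:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return best, 100.0 * matches / columns, columns


# --- isoelectric point grid search ----------------------------------------


def grid_search_pi(charge_fn, resolution=1e-4):
    """Scan pH in [0, 14] at fixed resolution; return the zero crossing."""
    best_ph, best_abs = 0.0, float("inf")
    steps = int(14 / resolution)
    for k in range(steps + 1):
        ph = k * resolution
        c = abs(charge_fn(ph))
        if c < best_abs:
            best_abs, best_ph = c, ph
    return best_ph
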