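"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: alignment identity is
recomputed by exhaustively enumerating every global alignment of two short
sequences, Levenshtein distance by the textbook DP, and the two-parent
chimera model by explicitly constructing every prefix+suffix model.
"""

from __future__ import annotations

MATCH = 1.0
MISMATCH = -2.0
GAP_OPEN = -10.0
GAP_EXTEND = -1.0


def _alignments(a: str, b: str):
    if not a and not b:
        yield []
        return
    if a and b:
        for rest in _alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest
    if a:
        for rest in _alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in _alignments(a, b[1:]):
            yield [("-", b[0])] + rest


def _score(cols) -> float:
    n = len(cols)
    score = 0.0
    for row in (0, 1):
        i = 0
        while i < n:
            if cols[i][row] == "-":
                j = i
                while j < n and cols[j][row] == "-":
                    j += 1
                if i > 0 and j < n:  # terminal gap runs are free
                    score += GAP_OPEN + (j - i - 1) * GAP_EXTEND
                i = j
            else:
                i += 1
    for ca, cb in cols:
        if ca != "-" and cb != "-":
            score += MATCH if ca == cb else MISMATCH
    return score


def _identity(cols) -> float:
    n = len(cols)
    first = 0
    while first < n and "-" in cols[first]:
        first += 1
    last = n - 1
    while last >= 0 and "-" in cols[last]:
        last -= 1
    if last < first:
        return 0.0
    counted = last - first + 1
    matches = sum(
        1 for i in range(first, last + 1) if cols[i][0] == cols[i][1] != "-"
    )
    return 100.0 * matches / counted


def alignment_identity_set(a: str, b: str) -> tuple[float, set[float]]:
    """(optimal score, identities of ALL optimal alignments) by enumeration.

    Co-optimal alignments can differ in identity (free end gaps allow short
    overlap alignments); the implementation may legitimately report any
    member of the set. Only practical for len <= ~7.
    """
    best: float | None = None
    idents: set[float] = set()
    for cols in _alignments(a, b):
        s = _score(cols)
        if best is None or s > best - 1e-9:
            if best is None or s > best + 1e-9:
                best, idents = s, {_identity(cols)}
            else:
                idents.add(_identity(cols))
    assert best is not None
    return best, idents


def levenshtein(a: str, b: str) -> int:
    """Textbook unit-cost edit distance DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def unoise_beta(d: int, alpha: float = 2.0) -> float:
    """Independent restatement of the abundance-skew threshold."""
    return 2.0 ** (-(alpha * d + 1.0))


def greedy_denoise_oracle(uniques, alpha: float = 2.0, minsize: int = 2):
    """Tiny independent denoiser: (id -> 'centroid'|'merged'|'discarded').

    ``uniques`` are (id, seq, size) tuples already in descending-size order.
    """
    centroids = []
    outcome = {}
    for uid, seq, size in uniques:
        merged = False
        for _, cseq, csize in centroids:
            d = levenshtein(seq, cseq)
            if size / csize <= unoise_beta(d, alpha):
                merged = True
                break
        if merged:
            outcome[uid] = "merged"
        elif size >= minsize:
            centroids.append((uid, seq, size))
            outcome[uid] = "centroid"
        else:
            outcome[uid] = "discarded"
    return outcome


def chimera_s2_bruteforce(candidate: str, ref_seqs: list[str], identity_fn) -> float:
    """Best two-segment model identity by explicit model construction.

    Enumerates every ordered reference pair and every breakpoint, builds the
    L-prefix + R-suffix model, and measures the candidate's identity to it
    with ``identity_fn``.
    """
    best = 0.0
    for i, left in enumerate(ref_seqs):
        for j, right in enumerate(ref_seqs):
            if i == j:
                continue
            for b in range(len(left) + 1):
                model = left[:b] + right[b:]
                if model:
                    best = max(best, identity_fn(candidate, model))
    return best
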