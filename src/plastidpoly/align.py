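"""Global pairwise alignment: affine-gap DP and anchor-chain-and-fill.

Near-identical plastomes are aligned by chaining maximal unique exact
matches (anchors) colinearly and closing the short inter-anchor gaps with an
affine-gap Needleman-Wunsch/Gotoh fill. Scoring: match +1, mismatch -1, gap
open -4, gap extend -1 (a k-long gap costs 4 + k). Equal-score gap
placements are canonicalized by shifting every gap run as far left as the
score allows, which makes alignments comparable across algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = 4  # penalty (positive), charged once per gap run
    gap_extend: int = 1  # penalty per gap column

    def pair(self, a: str, b: str) -> int:
        return self.match if a == b else self.mismatch


DEFAULT_SCORING = Scoring()

NEG = float("-inf")


def gotoh(a: str, b: str, scoring: Scoring = DEFAULT_SCORING,
          band: int | None = None) -> tuple[str, str]:
    """Optimal global alignment of two sequences; returns gapped strings.

    ``band`` restricts |i - j| around the main diagonal (plus the length
    difference); None means the full DP table.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return "-" * lb, b
    if lb == 0:
        return a, "-" * la
    go, ge = scoring.gap_open, scoring.gap_extend
    if band is not None:
        band = band + abs(la - lb)

    def in_band(i: int, j: int) -> bool:
        return band is None or abs(i - j) <= band

    # M: a[i-1] aligned to b[j-1]; X: gap in b (consumes a); Y: gap in a
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0
    for i in range(1, la + 1):
        if in_band(i, 0):
            X[i][0] = -(go + ge * i)
    for j in range(1, lb + 1):
        if in_band(0, j):
            Y[0][j] = -(go + ge * j)
    for i in range(1, la + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        ai = a[i - 1]
        jlo = 1 if band is None else max(1, i - band)
        jhi = lb if band is None else min(lb, i + band)
        for j in range(jlo, jhi + 1):
            s = scoring.pair(ai, b[j - 1])
            diag = max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            if diag > NEG:
                Mi[j] = diag + s
            Xi[j] = max(Mp[j] - go - ge, Xp[j] - ge, Yp[j] - go - ge)
            Yi[j] = max(Mi[j - 1] - go - ge, Yi[j - 1] - ge, Xi[j - 1] - go - ge)
    # traceback: prefer M, then X (gap in b), then Y
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    state = max(
        (("M", M[la][lb]), ("X", X[la][lb]), ("Y", Y[la][lb])),
        key=lambda t: t[1],
    )[0]
    while i > 0 or j > 0:
        if i > 0 and j > 0 and state == "M":
            s = scoring.pair(a[i - 1], b[j - 1])
            prev = M[i][j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = _pick(M[i][j], X[i][j], Y[i][j], prev)
        elif i > 0 and state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            cur = X[i][j]
            i -= 1
            if X[i][j] - scoring.gap_extend == cur:
                state = "X"
            else:
                state = _pick(
                    M[i][j] - scoring.gap_open - scoring.gap_extend,
                    NEG,
                    Y[i][j] - scoring.gap_open - scoring.gap_extend,
                    cur,
                    labels=("M", "X", "Y"),
                )
        elif j > 0 and state == "Y":
            out_a.append("-")
            out_b.append(b[j - 1])
            cur = Y[i][j]
            j -= 1
            if Y[i][j] - scoring.gap_extend == cur:
                state = "Y"
            else:
                state = _pick(
                    M[i][j] - scoring.gap_open - scoring.gap_extend,
                    X[i][j] - scoring.gap_open - scoring.gap_extend,
                    NEG,
                    cur,
                    labels=("M", "X", "Y"),
                )
        else:  # boundary: only one direction remains
            if i > 0:
                out_a.append(a[i - 1])
                out_b.append("-")
                i -= 1
            else:
                out_a.append("-")
                out_b.append(b[j - 1])
                j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _pick(m, x, y, target, labels=("M", "X", "Y")) -> str:
    for val, lab in ((m, labels[0]), (x, labels[1]), (y, labels[2])):
        if val == target:
            return lab
    # floating point never enters; integer scores must match one state
    raise RuntimeError("traceback failed")  # pragma: no cover


def alignment_score(a_aln: str, b_aln: str,
                    scoring: Scoring = DEFAULT_SCORING) -> int:
    """Score of a gapped alignment under the affine scheme."""
    if len(a_aln) != len(b_aln):
        raise ValueError("aligned strings differ in length")
    score = 0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(a_aln, b_aln):
        if ca == "-" and cb == "-":
            raise ValueError("double-gap column")
        if ca == "-":
            score -= scoring.gap_extend + (0 if in_gap_a else scoring.gap_open)
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= scoring.gap_extend + (0 if in_gap_b else scoring.gap_open)
            in_gap_a, in_gap_b = False, True
        else:
            score += scoring.pair(ca, cb)
            in_gap_a = in_gap_b = False
    return score


def normalize_gaps(a_aln: str, b_aln: str,
                   scoring: Scoring = DEFAULT_SCORING) -> tuple[str, str]:
    """Shift every gap run as far left as possible without changing the score.

    Canonical form for comparing equal-score alignments produced by
    different algorithms.
    """
    A, B = list(a_aln), list(b_aln)

    def settle(G: list[str], L: list[str]) -> bool:
        """G holds the gaps ('-'), L the letters; shift runs of '-' in G left."""
        changed = False
        i = 1
        n = len(G)
        while i < n:
            if G[i] == "-" and G[i - 1] != "-" and L[i - 1] != "-":
                e = i
                while e < n and G[e] == "-":
                    e += 1
                # move the letter G[i-1] from before the run to after it
                if scoring.pair(G[i - 1], L[e - 1]) == scoring.pair(G[i - 1], L[i - 1]):
                    G[i - 1 : e] = ["-"] * (e - i) + [G[i - 1]]
                    changed = True
                    # retry from the start of this run's new position
                    i = max(1, i - 1)
                    continue
                i = e
            else:
                i += 1
        return changed

    while True:
        c1 = settle(A, B)
        c2 = settle(B, A)
        if not (c1 or c2):
            break
    return "".join(A), "".join(B)


# ---------------------------------------------------------------------------
# anchors

def maximal_unique_matches(a: str, b: str, k: int = 20) -> list[tuple[int, int, int]]:
    """Maximal exact matches seeded at k-mers unique in both sequences.

    Returns (start_a, start_b, length), sorted by start_a.
    """
    def kmer_index(s: str):
        idx: dict[str, int] = {}
        dup: set[str] = set()
        for p in range(len(s) - k + 1):
            w = s[p : p + k]
            if w in idx:
                dup.add(w)
            else:
                idx[w] = p
        for w in dup:
            del idx[w]
        return idx

    ia = kmer_index(a)
    ib = kmer_index(b)
    covered: dict[int, int] = {}  # diagonal -> extended-until (a coordinate)
    anchors: list[tuple[int, int, int]] = []
    for w, pa in ia.items():
        pb = ib.get(w)
        if pb is None:
            continue
        diag = pa - pb
        if covered.get(diag, -1) >= pa:
            continue
        # extend maximally
        s_a, s_b = pa, pb
        while s_a > 0 and s_b > 0 and a[s_a - 1] == b[s_b - 1]:
            s_a -= 1
            s_b -= 1
        e_a, e_b = pa + k, pb + k
        while e_a < len(a) and e_b < len(b) and a[e_a] == b[e_b]:
            e_a += 1
            e_b += 1
        covered[diag] = e_a
        anchors.append((s_a, s_b, e_a - s_a))
    anchors = sorted(set(anchors))
    return anchors


def chain_anchors(anchors: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Heaviest colinear chain (by total anchor length), deterministic."""
    if not anchors:
        return []
    n = len(anchors)
    best = [0] * n
    prev = [-1] * n
    for i, (sa, sb, ln) in enumerate(anchors):
        best[i] = ln
        for j in range(i):
            pa, pb, pl = anchors[j]
            if pa + pl <= sa and pb + pl <= sb and best[j] + ln > best[i]:
                best[i] = best[j] + ln
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -anchors[i][0]))
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    return chain[::-1]


class TooDivergentError(ValueError):
    """Anchor chain covers too little of the reference for a reliable fill."""


MAX_FILL = 20_000  # largest inter-anchor segment the fill will attempt


def anchored_global_alignment(
    a: str,
    b: str,
    scoring: Scoring = DEFAULT_SCORING,
    k: int = 20,
    min_coverage: float = 0.5,
) -> tuple[str, str]:
    """Global alignment via anchor chaining + Gotoh gap fill, normalized."""
    chain = chain_anchors(maximal_unique_matches(a, b, k=k))
    cov = sum(ln for _, _, ln in chain)
    if cov < min_coverage * len(a):
        raise TooDivergentError(
            f"anchor chain covers {cov}/{len(a)} bp "
            f"({100 * cov / max(1, len(a)):.1f}%) of the reference"
        )
    out_a: list[str] = []
    out_b: list[str] = []
    ca = cb = 0
    for sa, sb, ln in chain + [(len(a), len(b), 0)]:
        seg_a, seg_b = a[ca:sa], b[cb:sb]
        if seg_a or seg_b:
            if max(len(seg_a), len(seg_b)) > MAX_FILL:
                raise TooDivergentError(
                    f"inter-anchor segment of {max(len(seg_a), len(seg_b))} bp"
                )
            band = None
            if len(seg_a) * len(seg_b) > 1_000_000:
                band = 200
            ga, gb = gotoh(seg_a, seg_b, scoring, band=band)
            out_a.append(ga)
            out_b.append(gb)
        out_a.append(a[sa : sa + ln])
        out_b.append(b[sb : sb + ln])
        ca, cb = sa + ln, sb + ln
    return normalize_gaps("".join(out_a), "".join(out_b), scoring)
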