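"""Long-range RNA loop–loop complementarity.

Kissing loops are antiparallel Watson–Crick duplexes between the unpaired
apical loops of two hairpins; branched kissing loops pair an apical loop
with an unpaired internal-loop/bulge strand.  The duplex model is ungapped:
the pair count between two strands is the maximum number of complementary
positions over all ungapped offsets of one strand against the reverse of the
other.  G-U wobbles are off by default (both kissing loops observed in the
Qβ genome are pure Watson–Crick) and can be enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}
_ALPHABET = set("ACGU")


def _check_alphabet(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    for ch in seq:
        if ch not in _ALPHABET:
            raise ValueError(f"invalid RNA character {ch!r}")
    return seq


def is_pair(a: str, b: str, allow_gu: bool = False) -> bool:
    p = (a, b)
    return p in _WC or (allow_gu and p in _GU)


def reverse_complement(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in reversed(_check_alphabet(seq)))


def antiparallel_pairs(seq1: str, seq2: str, allow_gu: bool = False) -> int:
    """Maximum number of paired positions when seq2 is reversed against
    seq1, over all ungapped offsets."""
    s1 = _check_alphabet(seq1)
    s2 = _check_alphabet(seq2)[::-1]
    if not s1 or not s2:
        raise ValueError("sequences must be nonempty")
    best = 0
    for off in range(-(len(s2) - 1), len(s1)):
        count = 0
        for k in range(len(s2)):
            i = off + k
            if 0 <= i < len(s1) and is_pair(s1[i], s2[k], allow_gu):
                count += 1
        best = max(best, count)
    return best


@dataclass
class KissingCandidate:
    """A complementary loop pair: donor/acceptor are 1-based inclusive
    nucleotide intervals; branched marks a loop-to-bulge pairing."""

    donor: tuple[int, int]
    donor_seq: str
    acceptor: tuple[int, int]
    acceptor_seq: str
    n_pairs: int
    branched: bool
    names: tuple[str, str] = ("", "")


def _loop_strands(pairs, n: int):
    """Classify maximal unpaired runs: apical loops (closed by a hairpin
    pair) vs internal/bulge strands (flanked by helices on both sides)."""
    partner = [0] * (n + 1)
    for i, j in pairs:
        if partner[i] or partner[j]:
            raise ValueError(f"conflicting base pairs at position {i if partner[i] else j}")
        partner[i], partner[j] = j, i
    apical, internal = [], []
    i = 1
    while i <= n:
        if partner[i]:
            i += 1
            continue
        j = i
        while j + 1 <= n and not partner[j + 1]:
            j += 1
        left = i - 1
        right = j + 1
        if left >= 1 and right <= n:
            if partner[left] == right:
                apical.append((i, j))
            else:
                internal.append((i, j))
        i = j + 1
    return apical, internal


def find_kissing(ss, seq: str, min_pairs: int = 4, allow_gu: bool = False) -> list[KissingCandidate]:
    """All apical×apical and apical×bulge strand pairs whose unpaired
    stretches form >= min_pairs antiparallel pairs.

    ``ss`` is a 1-based base-pair list consistent with ``seq``.  Candidates
    are sorted by descending pair count, then genome position.
    """
    if min_pairs < 2:
        raise ValueError("min_pairs must be >= 2")
    seq = _check_alphabet(seq)
    apical, internal = _loop_strands(ss, len(seq))
    internal = [s for s in internal if s[1] - s[0] + 1 >= min_pairs]
    out = []
    for ai, a in enumerate(apical):
        for b in apical[ai + 1 :]:
            n = antiparallel_pairs(seq[a[0] - 1 : a[1]], seq[b[0] - 1 : b[1]], allow_gu)
            if n >= min_pairs:
                out.append(
                    KissingCandidate(a, seq[a[0] - 1 : a[1]], b, seq[b[0] - 1 : b[1]], n, False)
                )
        for b in internal:
            if b == a:
                continue
            n = antiparallel_pairs(seq[a[0] - 1 : a[1]], seq[b[0] - 1 : b[1]], allow_gu)
            if n >= min_pairs:
                out.append(
                    KissingCandidate(a, seq[a[0] - 1 : a[1]], b, seq[b[0] - 1 : b[1]], n, True)
                )
    out.sort(key=lambda c: (-c.n_pairs, c.donor, c.acceptor))
    return out


def check_foldback(seq: str, tail_range, target_range, allow_gu: bool = False) -> int:
    """Antiparallel pair count between two equal-length subsequences (e.g.
    the genome's 3' tail folding back onto an upstream strand)."""
    seq = _check_alphabet(seq)
    (a1, a2), (b1, b2) = tuple(tail_range), tuple(target_range)
    for lo, hi in ((a1, a2), (b1, b2)):
        if not (1 <= lo <= hi <= len(seq)):
            raise ValueError(f"range {lo}-{hi} outside sequence of length {len(seq)}")
    if not (a2 < b1 or b2 < a1):
        raise ValueError(f"ranges {a1}-{a2} and {b1}-{b2} overlap")
    s1, s2 = seq[a1 - 1 : a2], seq[b1 - 1 : b2]
    if len(s1) != len(s2):
        raise ValueError("fold-back ranges must have equal lengths")
    s2r = s2[::-1]
    return sum(1 for x, y in zip(s1, s2r) if is_pair(x, y, allow_gu))
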