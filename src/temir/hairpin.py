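"""Hairpin folding and the rule-based pre-miRNA filter.

Candidate precursors are folded by base-pair maximization (Nussinov dynamic
programming) over Watson–Crick plus, optionally, G·U wobble pairs, with a
minimum hairpin-loop size of 3 nt.  The traceback is deterministic: at every
subproblem pairing the outer bases is preferred over bifurcation, and the
leftmost split point is taken on ties, so a sequence always folds to the same
dot-bracket string.

The filter that replaces a trained precursor classifier is an explicit rule
set over the fold: exactly one hairpin loop, no multiloops, a minimum longest
helix, a minimum paired fraction, a bounded terminal loop and a bounded
length.  A candidate fails with the list of named rules it violated, which is
what makes multi-branched candidates (the operative rejection mode in repeat
arrays) auditable rather than a black-box verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MIN_LOOP",
    "HairpinThresholds",
    "HairpinStructure",
    "HairpinVerdict",
    "fold_maxpair",
    "structure_features",
    "is_premirna_like",
]

MIN_LOOP = 3  # minimum unpaired nt enclosed by a pair

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}


def _pair_ok(wobble: bool) -> np.ndarray:
    ok = np.zeros((5, 5), dtype=bool)
    for a, b in (("A", "U"), ("G", "C")):
        ok[_CODE[a], _CODE[b]] = ok[_CODE[b], _CODE[a]] = True
    if wobble:
        ok[_CODE["G"], _CODE["U"]] = ok[_CODE["U"], _CODE["G"]] = True
    return ok


@dataclass
class HairpinThresholds:
    """Rule thresholds for the pre-miRNA filter (units: nt / base pairs)."""

    stem_min: int = 18          # longest contiguous helix, bp
    paired_min: float = 0.55    # fraction of nt paired
    loop_min: int = 3           # terminal loop size, nt
    loop_max: int = 20
    len_min: int = 70           # candidate length, nt
    len_max: int = 160
    wobble: bool = True


@dataclass
class HairpinStructure:
    """A folded sequence with its dot-bracket string and scanned features."""

    seq: str
    db: str
    n_pairs: int = 0
    n_hairpin_loops: int = 0
    n_multiloops: int = 0
    longest_stem: int = 0
    terminal_loop_size: int = 0

    @property
    def paired_fraction(self) -> float:
        return 2 * self.n_pairs / len(self.seq) if self.seq else 0.0


@dataclass
class HairpinVerdict:
    accepted: bool
    reasons: list[str] = field(default_factory=list)
    structure: HairpinStructure | None = None


def fold_maxpair(seq: str, wobble: bool = True) -> HairpinStructure:
    """Fold *seq* to a maximum-base-pair dot-bracket structure.

    N never pairs.  Raises ``ValueError`` for sequences shorter than 10 nt.
    """
    if len(seq) < MIN_LOOP + 2:
        raise ValueError(
            f"sequence too short to fold ({len(seq)} nt < {MIN_LOOP + 2})"
        )
    try:
        codes = np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"illegal nucleotide {exc.args[0]!r}") from exc
    ok = _pair_ok(wobble)
    n = len(codes)
    M = np.zeros((n, n), dtype=np.int32)
    # spans shorter than MIN_LOOP + 2 cannot pair; M already zero there
    for span in range(MIN_LOOP + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = np.zeros(n - span, dtype=np.int32)
        for d in range(1, span + 1):  # split after i+d-1
            np.maximum(best, M[i, i + d - 1] + M[i + d, j], out=best)
        pairable = ok[codes[i], codes[j]]
        cand = M[i + 1, j - 1] + 1
        best = np.where(pairable & (cand > best), cand, best)
        M[i, j] = best

    db = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP or M[i, j] == 0:
            continue
        if ok[codes[i], codes[j]] and M[i + 1, j - 1] + 1 == M[i, j]:
            db[i], db[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for d in range(1, j - i + 1):
            if M[i, i + d - 1] + M[i + d, j] == M[i, j]:
                stack.append((i, i + d - 1))
                stack.append((i + d, j))
                break
    return structure_features(HairpinStructure(seq=seq, db="".join(db)))


def _pair_table(db: str) -> list[int]:
    pt = [-1] * len(db)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"illegal dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unmatched '('")
    return pt


def structure_features(s: HairpinStructure) -> HairpinStructure:
    """Fill loop/stem features by a linear scan of the dot-bracket string."""
    pt = _pair_table(s.db)
    s.n_pairs = s.db.count("(")

    # hairpin loops and multiloops: classify the loop closed by each pair
    hairpin_sizes: list[int] = []
    n_multi = 0
    for i, j in ((i, pt[i]) for i in range(len(pt)) if pt[i] > i):
        children = 0
        unpaired = 0
        k = i + 1
        while k < j:
            if pt[k] > k:
                children += 1
                k = pt[k] + 1
            else:
                unpaired += 1
                k += 1
        if children == 0:
            hairpin_sizes.append(unpaired)
        elif children >= 2:
            n_multi += 1
    s.n_hairpin_loops = len(hairpin_sizes)
    s.n_multiloops = n_multi
    s.terminal_loop_size = hairpin_sizes[0] if hairpin_sizes else 0

    # longest contiguous stem: maximal run of stacked pairs
    longest = run = 0
    for i in range(len(pt)):
        if pt[i] > i:
            run = run + 1 if i > 0 and pt[i - 1] == pt[i] + 1 else 1
            longest = max(longest, run)
        # runs only advance on opening pairs
    s.longest_stem = longest
    return s


def is_premirna_like(
    seq: str, thresholds: HairpinThresholds | None = None
) -> HairpinVerdict:
    """Accept *seq* as a plausible single-stem pre-miRNA, or say why not."""
    t = thresholds or HairpinThresholds()
    reasons: list[str] = []
    if not t.len_min <= len(seq) <= t.len_max:
        reasons.append("length")
    if len(seq) < MIN_LOOP + 2:
        return HairpinVerdict(accepted=False, reasons=reasons or ["length"])
    s = fold_maxpair(seq, wobble=t.wobble)
    if s.n_hairpin_loops != 1 or s.n_multiloops > 0:
        reasons.append("multi-branched/multiple loops")
    if s.longest_stem < t.stem_min:
        reasons.append("stem")
    if s.paired_fraction < t.paired_min:
        reasons.append("paired-fraction")
    if s.n_hairpin_loops == 1 and not (
        t.loop_min <= s.terminal_loop_size <= t.loop_max
    ):
        reasons.append("terminal-loop")
    return HairpinVerdict(accepted=not reasons, reasons=reasons, structure=s)
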