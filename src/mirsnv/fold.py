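"""Minimum-free-energy RNA secondary structure for short mRNA windows.

The engine is a Nussinov-style dynamic program extended with a helix
stacking bonus, under a deliberately simple additive energy model:

* pair energies: GC -3.0, AU -2.0, GU -1.0 kcal/mol
* stacking bonus: -1.0 kcal/mol for each pair (i, j) whose inner
  neighbour (i+1, j-1) is also paired
* hairpin loops must enclose at least 3 unpaired residues
* pseudoknots are excluded; the empty structure scores 0

Absolute energies are therefore self-consistent but not comparable to
Turner nearest-neighbour values; the engine's purpose is reference vs
variant comparison of the same 71-nt window, where a shared
parameterization is what matters.

``enumerate_structures``/``fold_brute_force`` provide an independent
exhaustive oracle for short sequences, used by the test suite.
"""

from __future__ import annotations

import math
from collections.abc import Iterator

import numpy as np

from .types import FoldResult

PAIR_ENERGY: dict[tuple[str, str], float] = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}
STACK_BONUS = -1.0
MIN_HAIRPIN = 3  # minimum unpaired residues enclosed by a pair

_ALPHABET = set("ACGU")
INF = math.inf


def _pair_energy(a: str, b: str) -> float:
    return PAIR_ENERGY.get((a, b), INF)


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-RNA characters: {sorted(bad)}")


def _fill_tables(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """DP tables over 0-based intervals [i, j].

    W[i, j]: best energy of any structure on [i, j].
    V[i, j]: best energy given (i, j) paired (inf if unpairable).
    U[i, j]: best energy with i and j not paired to each other.
    E[i, j]: pair energy of (i, j) (inf if unpairable or hairpin too tight).
    """
    n = len(seq)
    W = np.zeros((n + 1, n + 1))
    V = np.full((n + 1, n + 1), INF)
    U = np.zeros((n + 1, n + 1))
    E = np.full((n, n), INF)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            E[i, j] = _pair_energy(seq[i], seq[j])

    # spans ascending; W/U defined with W[i, j] for j < i equal to 0 (empty)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            # V: (i, j) paired
            if E[i, j] < INF:
                inner = U[i + 1, j - 1] if j - 1 >= i + 1 else 0.0
                best_inner = inner
                if V[i + 1, j - 1] < INF:
                    best_inner = min(best_inner, V[i + 1, j - 1] + STACK_BONUS)
                V[i, j] = E[i, j] + best_inner
            # W and U: i unpaired, or i paired to some k (k < j for U, k <= j for W)
            best_u = W[i + 1, j]
            for k in range(i + MIN_HAIRPIN + 1, j):
                if V[i, k] < INF:
                    cand = V[i, k] + W[k + 1, j]
                    if cand < best_u:
                        best_u = cand
            U[i, j] = best_u
            best_w = best_u
            if V[i, j] < best_w:
                best_w = V[i, j]
            W[i, j] = best_w
    return W, V, U, E


def _traceback(seq: str, W: np.ndarray, V: np.ndarray, U: np.ndarray) -> set[tuple[int, int]]:
    """Recover one optimal pair set, preferring pairs with smallest i then smallest j."""
    n = len(seq)
    pairs: set[tuple[int, int]] = set()
    stack: list[tuple[int, int, str]] = [(0, n - 1, "W")]
    eps = 1e-9
    while stack:
        i, j, table = stack.pop()
        if j - i < MIN_HAIRPIN + 1:
            continue
        if table == "V":
            pairs.add((i, j))
            inner_i, inner_j = i + 1, j - 1
            if inner_j - inner_i >= MIN_HAIRPIN + 1:
                target = V[i, j] - PAIR_ENERGY[(seq[i], seq[j])]
                if (
                    V[inner_i, inner_j] < INF
                    and abs(V[inner_i, inner_j] + STACK_BONUS - target) < eps
                ):
                    stack.append((inner_i, inner_j, "V"))
                else:
                    stack.append((inner_i, inner_j, "U"))
            continue
        target = W[i, j] if table == "W" else U[i, j]
        if target >= -eps:
            continue
        # prefer pairing i to the smallest admissible k
        k_max = j if table == "W" else j - 1
        chosen = False
        for k in range(i + MIN_HAIRPIN + 1, k_max + 1):
            if V[i, k] < INF and abs(V[i, k] + W[k + 1, j] - target) < eps:
                stack.append((i, k, "V"))
                stack.append((k + 1, j, "W"))
                chosen = True
                break
        if not chosen:
            stack.append((i + 1, j, "W"))
    return pairs


def pairs_to_dotbracket(n: int, pairs: set[tuple[int, int]] | frozenset[tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def pairs_from_dotbracket(db: str) -> frozenset[tuple[int, int]]:
    """Parse a dot-bracket string back into a pair set; raises on imbalance."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx}")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} in dot-bracket")
    if stack:
        raise ValueError("unbalanced '(' remaining")
    return frozenset(pairs)


def structure_energy(seq: str, pairs: frozenset[tuple[int, int]] | set[tuple[int, int]]) -> float:
    """Energy of an explicit structure under the additive model (oracle helper)."""
    total = 0.0
    pairset = set(pairs)
    for i, j in pairset:
        e = _pair_energy(seq[i], seq[j])
        if e is INF:
            raise ValueError(f"inadmissible pair ({i},{j}): {seq[i]}-{seq[j]}")
        total += e
        if (i + 1, j - 1) in pairset:
            total += STACK_BONUS
    return total


def fold_mfe(seq: str) -> FoldResult:
    """Fold one RNA sequence, returning a single optimal structure.

    Ties are broken deterministically: among optimal structures the
    traceback pairs the smallest available 5' index with the smallest
    admissible partner.
    """
    if len(seq) < 1:
        raise ValueError("sequence must be non-empty")
    seq = seq.upper().replace("T", "U")
    _check_alphabet(seq)
    n = len(seq)
    if n < MIN_HAIRPIN + 2:
        return FoldResult(seq, "." * n, 0.0, frozenset())
    W, V, U, _ = _fill_tables(seq)
    pairs = frozenset(_traceback(seq, W, V, U))
    energy = float(W[0, n - 1])
    return FoldResult(seq, pairs_to_dotbracket(n, pairs), energy, pairs)


def enumerate_structures(seq: str) -> Iterator[frozenset[tuple[int, int]]]:
    """Yield every non-crossing structure with hairpin >= MIN_HAIRPIN.

    Exhaustive; intended for sequences of length <~ 14 as an independent
    oracle against the dynamic program.
    """
    seq = seq.upper().replace("T", "U")
    _check_alphabet(seq)
    n = len(seq)

    def rec(i: int, j: int) -> Iterator[frozenset[tuple[int, int]]]:
        if j - i < MIN_HAIRPIN + 1:
            yield frozenset()
            return
        # case: i unpaired
        yield from rec(i + 1, j)
        # case: i paired to k
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if (seq[i], seq[k]) in PAIR_ENERGY:
                for inner in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield inner | right | {(i, k)}

    yield from rec(0, n - 1)


def fold_brute_force(seq: str) -> float:
    """Exhaustive-minimum energy over all admissible structures (oracle)."""
    rna = seq.upper().replace("T", "U")
    return min(structure_energy(rna, s) for s in enumerate_structures(rna))


def bp_distance(a: FoldResult, b: FoldResult) -> int:
    """Base-pair distance: |symmetric difference| of the two pair sets."""
    if len(a.sequence) != len(b.sequence):
        raise ValueError("bp_distance requires equal-length sequences")
    return len(a.pairs ^ b.pairs)


def compare_pair(window_pair) -> "StructureDelta":
    """Fold both windows of a UtrWindowPair and summarize the change."""
    from .types import StructureDelta

    ref = fold_mfe(window_pair.ref_window)
    alt = fold_mfe(window_pair.alt_window)
    return StructureDelta(
        variant_key=window_pair.variant_key,
        gene_id=window_pair.gene_id,
        ref_energy=ref.energy,
        alt_energy=alt.energy,
        bp_distance=bp_distance(ref, alt),
    )
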