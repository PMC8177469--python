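"""miRNA binding-site prediction on 3'-UTR windows and gain/loss calling.

Two independent predictors are combined by consensus:

1. a canonical seed-match scanner (8mer / 7mer-m8 / 7mer-A1 / 6mer site
   taxonomy, strict Watson-Crick in the seed, no G:U), and
2. a hybridization-energy dynamic program over antiparallel
   inter-molecular pairings (no intramolecular structure) with a simple
   additive score.

A miRNA is reported for a window only when the seed scanner finds a
canonical site overlapping the SNV position AND the duplex energy over
that site plus flanking context clears the energy threshold — both
predictors must agree, and the site must overlap the variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .types import GainLossRecord, MatureMiRNA, TargetSite

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SITE_HIERARCHY = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1}


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def comp_rna(base: str) -> str:
    return base.translate(_RNA_COMPLEMENT)


@dataclass(frozen=True)
class DuplexParams:
    """Additive inter-molecular hybridization score (kcal/mol)."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    stack: float = -1.0  # bonus per contiguous adjacent pair
    loop_open: float = 2.0  # bulge / internal loop opening
    loop_ext: float = 0.5  # per unpaired residue inside a loop

    def pair_energy(self, a: str, b: str) -> float | None:
        pair = frozenset((a, b))
        if pair == frozenset("GC"):
            return self.gc
        if pair == frozenset("AU"):
            return self.au
        if pair == frozenset("GU"):
            return self.gu
        return None


DEFAULT_DUPLEX_PARAMS = DuplexParams()


def seed_sites(window: str, mirna: MatureMiRNA) -> list[TargetSite]:
    """Scan a window (RNA, 5'->3') for canonical seed-match sites.

    Site definitions relative to the miRNA seed span (default 2..8):
    the target core is the reverse complement of seed positions
    seed_start..seed_end-1; an exact match at the position opposite
    seed_end upgrades to the -m8 variants, and an A opposite miRNA
    position 1 upgrades to the -A1/8mer variants.  Only the maximal site
    type is reported per locus.  Coordinates are 1-based inclusive.
    """
    window = window.upper().replace("T", "U")
    m = mirna.sequence
    core = revcomp_rna(m[mirna.seed_start - 1 : mirna.seed_end - 1])
    m8_comp = comp_rna(m[mirna.seed_end - 1])
    sites: list[TargetSite] = []
    core_len = len(core)
    start = 0
    while True:
        p = window.find(core, start)
        if p < 0:
            break
        start = p + 1
        has_m8 = p > 0 and window[p - 1] == m8_comp
        has_a1 = p + core_len < len(window) and window[p + core_len] == "A"
        if has_m8 and has_a1:
            site_type, lo, hi = "8mer", p - 1, p + core_len
        elif has_m8:
            site_type, lo, hi = "7mer-m8", p - 1, p + core_len - 1
        elif has_a1:
            site_type, lo, hi = "7mer-A1", p, p + core_len
        else:
            site_type, lo, hi = "6mer", p, p + core_len - 1
        sites.append(TargetSite(mirna.mirna_id, lo + 1, hi + 1, site_type))
    return sites


def duplex_energy(
    target: str, mirna: MatureMiRNA | str, params: DuplexParams = DEFAULT_DUPLEX_PARAMS
) -> tuple[float, int, str]:
    """Minimum hybridization energy of target (5'->3') vs miRNA (5'->3').

    Dynamic program over antiparallel inter-molecular pairings: base pairs
    must be non-crossing after reversing the miRNA; contiguous pairs earn
    the stacking bonus, interruptions pay a loop opening plus a per-residue
    extension; dangling ends are free.  The empty pairing scores 0, so the
    returned energy is never positive.

    Returns (energy, paired_count, pairing) where pairing lists the base
    pairs as ``t<i>:m<j>`` in original 1-based coordinates of each strand.
    """
    mseq = mirna.sequence if isinstance(mirna, MatureMiRNA) else mirna
    t = target.upper().replace("T", "U")
    q = mseq.upper().replace("T", "U")[::-1]  # reversed miRNA: pairs now co-linear
    n, m = len(t), len(q)
    if n == 0 or m == 0:
        raise ValueError("both sequences must be non-empty")
    # D[i][j]: best energy of a duplex whose last (3'-most on target) pair is (i, j)
    D = [[0.0] * m for _ in range(n)]
    back: list[list[tuple[int, int] | None]] = [[None] * m for _ in range(n)]
    best_energy = 0.0
    best_cell: tuple[int, int] | None = None
    for i in range(n):
        for j in range(m):
            e = params.pair_energy(t[i], q[j])
            if e is None:
                D[i][j] = float("inf")
                continue
            best_prev = 0.0
            best_ptr: tuple[int, int] | None = None
            for pi in range(i):
                row = D[pi]
                for pj in range(j):
                    prev = row[pj]
                    if prev == float("inf"):
                        continue
                    a = i - pi - 1
                    b = j - pj - 1
                    if a == 0 and b == 0:
                        cost = params.stack
                    else:
                        cost = params.loop_open + params.loop_ext * (a + b)
                    cand = prev + cost
                    if cand < best_prev:
                        best_prev = cand
                        best_ptr = (pi, pj)
            D[i][j] = e + best_prev
            back[i][j] = best_ptr
            if D[i][j] < best_energy:
                best_energy = D[i][j]
                best_cell = (i, j)
    pairs: list[tuple[int, int]] = []
    cell = best_cell
    while cell is not None:
        i, j = cell
        pairs.append((i + 1, m - j))  # back to original 5'->3' miRNA coordinates
        cell = back[i][j]
    pairs.reverse()
    pairing = ",".join(f"t{i}:m{j}" for i, j in pairs)
    return best_energy, len(pairs), pairing


def duplex_brute_force(
    target: str, mirna: str, params: DuplexParams = DEFAULT_DUPLEX_PARAMS
) -> float:
    """Exhaustive minimum over all antiparallel pairings (oracle, lengths <= ~8)."""
    t = target.upper().replace("T", "U")
    q = mirna.upper().replace("T", "U")[::-1]
    n, m = len(t), len(q)
    best = 0.0
    max_k = min(n, m)
    for k in range(1, max_k + 1):
        for t_idx in combinations(range(n), k):
            for q_idx in combinations(range(m), k):
                energy = 0.0
                ok = True
                for step, (i, j) in enumerate(zip(t_idx, q_idx)):
                    e = params.pair_energy(t[i], q[j])
                    if e is None:
                        ok = False
                        break
                    energy += e
                    if step > 0:
                        a = i - t_idx[step - 1] - 1
                        b = j - q_idx[step - 1] - 1
                        if a == 0 and b == 0:
                            energy += params.stack
                        else:
                            energy += params.loop_open + params.loop_ext * (a + b)
                if ok and energy < best:
                    best = energy
    return best


def consensus_sites(
    window: str,
    snv_index: int,
    mirna_lib: list[MatureMiRNA],
    energy_threshold: float = -8.0,
    context: int = 10,
    params: DuplexParams = DEFAULT_DUPLEX_PARAMS,
) -> list[TargetSite]:
    """Sites supported by both predictors and overlapping the SNV.

    For each miRNA, seed sites whose interval contains ``snv_index``
    (1-based window coordinate) are ranked by site-type hierarchy then
    position; the best is kept if the duplex energy over the site plus
    ``context`` nt of flank on each side is <= ``energy_threshold``.
    """
    window = window.upper().replace("T", "U")
    if not 1 <= snv_index <= len(window):
        raise ValueError("snv_index outside window")
    out: list[TargetSite] = []
    for m in mirna_lib:
        overlapping = [s for s in seed_sites(window, m) if s.start <= snv_index <= s.end]
        if not overlapping:
            continue
        site = max(overlapping, key=lambda s: (SITE_HIERARCHY[s.site_type], -s.start))
        lo = max(1, site.start - context)
        hi = min(len(window), site.end + context)
        energy, paired, _ = duplex_energy(window[lo - 1 : hi], m, params)
        if energy <= energy_threshold:
            out.append(
                TargetSite(
                    mirna_id=m.mirna_id,
                    start=site.start,
                    end=site.end,
                    site_type=site.site_type,
                    duplex_energy=energy,
                    paired_count=paired,
                    agreement="both",
                )
            )
    return out


def diff_sites(
    gene_id: str,
    variant_key: tuple[str, int, str, str],
    ref_sites: list[TargetSite],
    alt_sites: list[TargetSite],
) -> GainLossRecord:
    """miRNAs present on the variant window only (gained) or reference only (lost)."""
    ref_ids = {s.mirna_id for s in ref_sites}
    alt_ids = {s.mirna_id for s in alt_sites}
    return GainLossRecord(
        gene_id=gene_id,
        variant_key=variant_key,
        gained=frozenset(alt_ids - ref_ids),
        lost=frozenset(ref_ids - alt_ids),
    )
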