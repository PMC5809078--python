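"""Watson-Crick pair detection, duplex assembly and curation.

Pairs are called from geometry alone (complementarity, C1'-C1'
distance, canonical donor-acceptor contacts, base-plane angle), grouped
into maximal antiparallel runs, and curated the way a careful manual
screen would: dangling single-stranded ends are trimmed so step indices
refer to true pairs, and flipped-out bases are flagged so kinks next to
them are annotated rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._standard_bases import RING_ATOMS, wc_hbond_atoms
from .structure_io import ResidueRecord, StructureModel, base_letter

__all__ = [
    "BasePair",
    "Duplex",
    "detect_base_pairs",
    "assemble_duplexes",
    "trim_dangling_ends",
    "detect_flipped_bases",
    "build_curated_duplexes",
]

# pair-acceptance thresholds; chosen to keep sharply kinked steps
# (roll up to ~55 deg) while rejecting stacked non-pairs
C1C1_RANGE = (8.0, 12.5)   # angstrom
HBOND_MAX = 3.6            # angstrom
PLANE_ANGLE_MAX = 65.0     # degrees
MIN_HBONDS = 2


@dataclass
class BasePair:
    res_I: ResidueRecord
    res_II: ResidueRecord
    n_hbonds: int
    c1c1_distance: float
    is_watson_crick: bool = True


@dataclass
class Duplex:
    pairs: list[BasePair]
    sequence_I: str
    trimmed_5p: int = 0
    trimmed_3p: int = 0
    flipped_positions: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.pairs)


def _ring_coords(residue: ResidueRecord) -> np.ndarray | None:
    letter = base_letter(residue)
    if letter is None:
        return None
    coords = [residue.atom(n).position for n in RING_ATOMS[letter]
              if residue.atom(n) is not None]
    if len(coords) < 4:
        return None
    return np.array(coords)


def _base_normal(residue: ResidueRecord) -> np.ndarray | None:
    coords = _ring_coords(residue)
    if coords is None:
        return None
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def base_centroid(residue: ResidueRecord) -> np.ndarray | None:
    coords = _ring_coords(residue)
    return None if coords is None else coords.mean(axis=0)


def count_wc_hbonds(res_a: ResidueRecord, res_b: ResidueRecord,
                    max_dist: float = HBOND_MAX) -> int:
    """Number of canonical WC donor-acceptor contacts within max_dist."""
    la, lb = base_letter(res_a), base_letter(res_b)
    if la is None or lb is None:
        return 0
    n = 0
    for name_a, name_b in wc_hbond_atoms(la, lb):
        atom_a, atom_b = res_a.atom(name_a), res_b.atom(name_b)
        if atom_a is None or atom_b is None:
            continue
        if np.linalg.norm(atom_a.position - atom_b.position) <= max_dist:
            n += 1
    return n


def detect_base_pairs(model: StructureModel) -> list[BasePair]:
    """Geometric Watson-Crick pair detection.

    A candidate pair must be complementary (A:T or G:C), have its
    C1'-C1' distance in [8.0, 12.5] A, at least two canonical
    donor-acceptor contacts within 3.6 A, and base planes inclined by
    at most 65 degrees.  Each base joins at most one pair; candidates
    are accepted greedily by descending contact count (ties: smaller
    C1'-C1' distance).
    """
    nucleotides = [r for r in model.iter_residues()
                   if r.kind == "dna_nucleotide" and r.atom("C1'") is not None
                   and _ring_coords(r) is not None]
    candidates = []
    for i, ra in enumerate(nucleotides):
        la = base_letter(ra)
        for rb in nucleotides[i + 1:]:
            lb = base_letter(rb)
            if {la, lb} not in ({"A", "T"}, {"G", "C"}):
                continue
            d = float(np.linalg.norm(ra.atom("C1'").position - rb.atom("C1'").position))
            if not (C1C1_RANGE[0] <= d <= C1C1_RANGE[1]):
                continue
            n_hb = count_wc_hbonds(ra, rb)
            if n_hb < MIN_HBONDS:
                continue
            na, nb = _base_normal(ra), _base_normal(rb)
            angle = np.degrees(np.arccos(np.clip(abs(float(na @ nb)), 0.0, 1.0)))
            if angle > PLANE_ANGLE_MAX:
                continue
            candidates.append((n_hb, d, ra, rb))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    used: set[tuple] = set()
    pairs = []
    for n_hb, d, ra, rb in candidates:
        if ra.id in used or rb.id in used:
            continue
        used.update((ra.id, rb.id))
        pairs.append(BasePair(res_I=ra, res_II=rb, n_hbonds=n_hb,
                              c1c1_distance=d, is_watson_crick=True))
    return pairs


def assemble_duplexes(pairs: list[BasePair], model: StructureModel) -> list[Duplex]:
    """Partition pairs into maximal antiparallel runs.

    Consecutive pairs must have chain-adjacent strand-I residues and
    reverse-adjacent strand-II residues.  Runs of length >= 2 each
    become one Duplex; several independent double helices in one model
    yield several duplexes.
    """
    def pos(res: ResidueRecord) -> tuple[str, int]:
        return (res.chain_id, model.residue_position(res))

    oriented = []
    for p in pairs:
        a, b = pos(p.res_I), pos(p.res_II)
        if b < a:
            p = BasePair(res_I=p.res_II, res_II=p.res_I, n_hbonds=p.n_hbonds,
                         c1c1_distance=p.c1c1_distance,
                         is_watson_crick=p.is_watson_crick)
        oriented.append(p)
    oriented.sort(key=lambda p: pos(p.res_I))

    duplexes: list[Duplex] = []
    run: list[BasePair] = []

    def close_run():
        if len(run) >= 2:
            seq = "".join(base_letter(p.res_I) or "N" for p in run)
            duplexes.append(Duplex(pairs=list(run), sequence_I=seq))
        run.clear()

    for p in oriented:
        if run:
            prev = run[-1]
            ca, ia = pos(prev.res_I)
            cb, ib = pos(p.res_I)
            cIIa, iIIa = pos(prev.res_II)
            cIIb, iIIb = pos(p.res_II)
            adjacent = (ca == cb and ib == ia + 1
                        and cIIa == cIIb and iIIb == iIIa - 1)
            if not adjacent:
                close_run()
        run.append(p)
    close_run()
    return duplexes


def _unpaired_run(chain: list[ResidueRecord], start: int, direction: int,
                  paired_ids: set) -> int:
    """Count contiguous unpaired DNA nucleotides from ``start`` moving
    ``direction`` (+1/-1) toward the chain terminus."""
    n = 0
    i = start
    while 0 <= i < len(chain):
        res = chain[i]
        if res.kind != "dna_nucleotide" or res.id in paired_ids:
            break
        n += 1
        i += direction
    return n


def trim_dangling_ends(duplex: Duplex, model: StructureModel,
                       paired_ids: set | None = None) -> Duplex:
    """Record dangling single-stranded overhangs beyond the paired core.

    Unpaired terminal nucleotides on either strand are counted into
    trimmed_5p / trimmed_3p (named for the strand-I orientation of the
    duplex end they flank); the paired core and hence all step indices
    are unchanged.  This is the register-correcting fix for automated
    analyses confused by dangling ends.  ``paired_ids`` may carry the
    residues paired anywhere in the model (so a neighboring duplex's
    bases are never mistaken for overhangs); it defaults to this
    duplex's own pairs.
    """
    paired = paired_ids if paired_ids is not None else (
        {p.res_I.id for p in duplex.pairs} | {p.res_II.id for p in duplex.pairs})
    first, last = duplex.pairs[0], duplex.pairs[-1]

    chain_I_first = model.chains[first.res_I.chain_id]
    chain_II_first = model.chains[first.res_II.chain_id]
    chain_I_last = model.chains[last.res_I.chain_id]
    chain_II_last = model.chains[last.res_II.chain_id]

    i_first = model.residue_position(first.res_I)
    ii_first = model.residue_position(first.res_II)
    i_last = model.residue_position(last.res_I)
    ii_last = model.residue_position(last.res_II)

    trimmed_5p = (_unpaired_run(chain_I_first, i_first - 1, -1, paired)
                  + _unpaired_run(chain_II_first, ii_first + 1, +1, paired))
    trimmed_3p = (_unpaired_run(chain_I_last, i_last + 1, +1, paired)
                  + _unpaired_run(chain_II_last, ii_last - 1, -1, paired))
    return Duplex(pairs=duplex.pairs, sequence_I=duplex.sequence_I,
                  trimmed_5p=trimmed_5p, trimmed_3p=trimmed_3p,
                  flipped_positions=set(duplex.flipped_positions))


FLIP_AXIS_DIST = 4.0  # angstrom, centroid offset from the local helix axis


def _pair_origin(pair: BasePair) -> np.ndarray:
    """Pair origin from fitted base frames (an on-axis point); falls
    back to the ring-centroid midpoint when fitting fails."""
    from .helix_geometry import fit_base_frame

    try:
        f1, _ = fit_base_frame(pair.res_I)
        f2, _ = fit_base_frame(pair.res_II)
        return (f1.origin + f2.origin) / 2.0
    except ValueError:
        ca, cb = base_centroid(pair.res_I), base_centroid(pair.res_II)
        if ca is None or cb is None:
            raise
        return (ca + cb) / 2.0


def _local_axis_distance(point: np.ndarray, origins: list[np.ndarray]) -> float:
    """Distance from a point to the local helix-axis line through the
    two nearest pair origins."""
    if len(origins) == 1:
        return float(np.linalg.norm(point - origins[0]))
    dists = [np.linalg.norm(point - o) for o in origins]
    order = np.argsort(dists)
    a, b = origins[order[0]], origins[order[1]]
    u = b - a
    u = u / np.linalg.norm(u)
    v = point - a
    return float(np.linalg.norm(v - (v @ u) * u))


def detect_flipped_bases(model: StructureModel, duplex: Duplex,
                         paired_ids: set | None = None) -> set[int]:
    """Flag flipped-out bases in and around a duplex.

    Positions are 1-based in the duplex's strand-I register (pair 1 is
    index 1; an unpaired base right past the 3' end is index len+1,
    right before the 5' end index 0).  A position is flagged when its
    nominal pair has fewer than two canonical contacts, or when an
    unpaired base's ring centroid lies more than 4.0 A from the local
    helix axis interpolated between flanking pair origins.  A genuinely
    kinked but intact pair is not flagged.
    """
    flagged: set[int] = set()
    origins = []
    for p in duplex.pairs:
        try:
            origins.append(_pair_origin(p))
        except ValueError:
            pass
    if not origins:
        return flagged

    for idx, p in enumerate(duplex.pairs, start=1):
        if count_wc_hbonds(p.res_I, p.res_II) < MIN_HBONDS:
            flagged.add(idx)

    paired = paired_ids if paired_ids is not None else (
        {p.res_I.id for p in duplex.pairs} | {p.res_II.id for p in duplex.pairs})
    chain_I = model.chains[duplex.pairs[0].res_I.chain_id]
    i_first = model.residue_position(duplex.pairs[0].res_I)
    i_last = model.residue_position(duplex.pairs[-1].res_I)
    chain_II = model.chains[duplex.pairs[0].res_II.chain_id]
    ii_first = model.residue_position(duplex.pairs[0].res_II)
    ii_last = model.residue_position(duplex.pairs[-1].res_II)

    candidates: list[tuple[int, ResidueRecord, ResidueRecord | None]] = []
    for offset in (1, 2):
        for chain, i0, step, partner_chain, p0, p_step, index in (
            (chain_I, i_first, -offset, chain_II, ii_first, +offset, 1 - offset),
            (chain_I, i_last, +offset, chain_II, ii_last, -offset, len(duplex.pairs) + offset),
            (chain_II, ii_first, +offset, chain_I, i_first, -offset, 1 - offset),
            (chain_II, ii_last, -offset, chain_I, i_last, +offset, len(duplex.pairs) + offset),
        ):
            j = i0 + step
            k = p0 + p_step
            if 0 <= j < len(chain):
                partner = partner_chain[k] if 0 <= k < len(partner_chain) else None
                candidates.append((index, chain[j], partner))
    for index, res, partner in candidates:
        if res.kind != "dna_nucleotide" or res.id in paired:
            continue
        # a base whose register partner exists but makes no WC contacts
        # is flipped out; a base with no partner at all is a dangling
        # end (handled by trimming, not flagged here)
        if (partner is not None and partner.kind == "dna_nucleotide"
                and partner.id not in paired
                and count_wc_hbonds(res, partner) < MIN_HBONDS):
            flagged.add(index)
            continue
        centroid = base_centroid(res)
        if centroid is None:
            continue
        if _local_axis_distance(centroid, origins) > FLIP_AXIS_DIST:
            flagged.add(index)
    return flagged


def build_curated_duplexes(model: StructureModel) -> list[Duplex]:
    """Full curation pipeline: detect pairs, assemble runs, trim
    dangling ends and attach flip-out flags."""
    pairs = detect_base_pairs(model)
    duplexes = assemble_duplexes(pairs, model)
    all_paired = {p.res_I.id for p in pairs} | {p.res_II.id for p in pairs}
    curated = []
    for d in duplexes:
        d = trim_dangling_ends(d, model, paired_ids=all_paired)
        d.flipped_positions = detect_flipped_bases(model, d, paired_ids=all_paired)
        curated.append(d)
    return curated


def duplex_to_tsv(duplex: Duplex) -> str:
    """Pair-level summary table as TSV text."""
    lines = ["pair_index\tres_I\tres_II\tn_hbonds\tc1c1_distance\tflags"]
    for i, p in enumerate(duplex.pairs, start=1):
        flags = "flipped" if i in duplex.flipped_positions else "-"
        lines.append(
            f"{i}\t{p.res_I.chain_id}{p.res_I.number}{p.res_I.name}\t"
            f"{p.res_II.chain_id}{p.res_II.number}{p.res_II.name}\t"
            f"{p.n_hbonds}\t{p.c1c1_distance:.2f}\t{flags}"
        )
    return "\n".join(lines) + "\n"
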