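"""Sequence-based miRNA target prediction.

Canonical seed-match detection on 3'UTRs and circRNAs, a transparent
0-100 site score, and a nearest-neighbor duplex free energy, combined
into a two-filter predictor (score >= site_score_min AND energy <=
energy_max_kcal) that emulates intersecting a seed-based predictor
with an energy-based one.

Site taxonomy (miRNA positions are 1-based, 5' -> 3'):

* 6mer     — target reverse-complements miRNA positions 2-7
* 7mer-m8  — 6mer plus a match to miRNA position 8
* 7mer-A1  — 6mer plus an A on the target opposite miRNA position 1
* 8mer     — both extensions

The target site is reported by the 0-based start of the 6mer core
match on the target, forward orientation (targets are given 5'->3';
no reverse-strand scan).  circRNAs are scanned as a linear sequence
with the first 7 nt appended at the end so sites spanning the
back-splice junction are found.

The site score is declared, not fitted: base points per site type
(6mer 30, 7mer-A1 50, 7mer-m8 60, 8mer 75) plus an AU-context bonus of
25 x the A/U fraction of the +-30 nt flanks, clamped to [0, 100].  The
duplex energy is a helix-initiation penalty of +4.09 kcal/mol plus
Turner-style stacking terms over the seed duplex and the longest
contiguous 3'-supplementary block (miRNA positions 12-17, G:U wobble
allowed there but not in the seed).  All stacking terms are negative,
so more pairing always means lower (more stable) energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

SITE_BASE_SCORE = {"6mer": 30.0, "7mer-A1": 50.0, "7mer-m8": 60.0, "8mer": 75.0}
SITE_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}

INITIATION_KCAL = 4.09

#: Turner-style RNA nearest-neighbor stack free energies (kcal/mol,
#: 37 C).  Keys are (miRNA dinucleotide read 5'->3', target
#: dinucleotide of the same two steps): key ("GA", "CU") is the step
#: of base pairs (G:C) then (A:U).  10 Watson-Crick classes (Turner
#: 2004 values), 8 single-wobble and 3 double-wobble classes
#: (representative magnitudes); the rotational closure below expands
#: them to all 36 valid steps.  Every entry is strictly negative, so
#: extending a helix always stabilizes it.
_STACK_SEED = {
    # WC-WC
    ("AA", "UU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08,
    ("CA", "GU"): -2.11,
    ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
    # one G:U wobble pair in the step
    ("AG", "UU"): -0.55,
    ("AU", "UG"): -1.36,
    ("CG", "GU"): -1.41,
    ("CU", "GG"): -2.11,
    ("GG", "CU"): -1.53,
    ("GU", "CG"): -2.51,
    ("UG", "AU"): -1.27,
    ("UU", "AG"): -1.00,
    # both pairs wobble
    ("GG", "UU"): -0.50,
    ("GU", "UG"): -0.30,
    ("UG", "GU"): -0.30,
}


def _close_stack_table(seed: dict) -> dict:
    """Close under the duplex rotational symmetry
    E(5'XY3'/3'WZ5') = E(5'ZW3'/3'YX5')."""
    table = dict(seed)
    for (m, t), e in seed.items():
        table.setdefault((t[::-1], m[::-1]), e)
    return table


STACK_TABLE = _close_stack_table(_STACK_SEED)


def _is_pair(x: str, y: str, wobble: bool) -> bool:
    if COMPLEMENT.get(x) == y:
        return True
    return wobble and {x, y} == {"G", "U"}


def stack_energy(pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
    """Free energy of stacking pair2 on pair1 (miRNA strand 5'->3')."""
    key = (pair1[0] + pair2[0], pair1[1] + pair2[1])
    try:
        return STACK_TABLE[key]
    except KeyError:
        raise ValueError(f"not a stackable step: {key}") from None


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass
class BindingSite:
    mirna_id: str
    target_id: str
    target_kind: str          # utr3 | circRNA
    position: int             # 0-based start of the 6mer core on the target
    site_type: str
    score: float = 0.0
    energy_kcal: float = 0.0


@dataclass
class TargetPair:
    mirna_id: str
    target_id: str
    target_kind: str
    best_site: BindingSite
    n_sites: int


def _scan_linear(mirna: SequenceRecord, target_seq: str, target: SequenceRecord,
                 limit: int | None = None) -> list[BindingSite]:
    if len(mirna.seq) < 8:
        raise ValueError(f"{mirna.id}: miRNA shorter than 8 nt")
    core = revcomp(mirna.seq[1:7])          # matches miRNA positions 2-7
    if "N" in core or "N" in mirna.seq[:8]:
        raise ValueError(f"{mirna.id}: ambiguous base in seed region")
    m8c = COMPLEMENT[mirna.seq[7]]
    sites = []
    start = target_seq.find(core)
    while start != -1:
        if limit is None or start < limit:
            has_m8 = start > 0 and target_seq[start - 1] == m8c
            has_a1 = start + 6 < len(target_seq) and target_seq[start + 6] == "A"
            site_type = ("8mer" if has_m8 and has_a1 else
                         "7mer-m8" if has_m8 else
                         "7mer-A1" if has_a1 else "6mer")
            sites.append(BindingSite(mirna.id, target.id, target.kind, start, site_type))
        start = target_seq.find(core, start + 1)
    return sites


def scan_sequence(target: SequenceRecord) -> str:
    """The string actually scanned: circRNAs get their first 7 nt
    appended to expose back-splice-junction-spanning sites."""
    if target.kind == "circRNA":
        return target.seq + target.seq[:7]
    return target.seq


def site_scan(mirna: SequenceRecord, target: SequenceRecord) -> list[BindingSite]:
    """All seed-match sites of ``mirna`` on ``target`` (every matching
    window reported; no overlap resolution)."""
    if len(target.seq) < 8:
        raise ValueError(f"{target.id}: target shorter than 8 nt")
    seq = scan_sequence(target)
    limit = len(target.seq) if target.kind == "circRNA" else None
    return _scan_linear(mirna, seq, target, limit=limit)


def site_span(site: BindingSite) -> tuple[int, int]:
    """Half-open span of the full matched pattern on the scan string."""
    start = site.position - (1 if site.site_type in ("7mer-m8", "8mer") else 0)
    end = site.position + 6 + (1 if site.site_type in ("7mer-A1", "8mer") else 0)
    return start, end


def site_score(site: BindingSite, target: SequenceRecord, flank: int = 30) -> float:
    """Declared 0-100 site score: type base points + AU-context bonus."""
    seq = scan_sequence(target)
    start, end = site_span(site)
    flanks = seq[max(0, start - flank):start] + seq[end:end + flank]
    au = sum(1 for b in flanks if b in "AU") / len(flanks) if flanks else 0.0
    return float(np.clip(SITE_BASE_SCORE[site.site_type] + 25.0 * au, 0.0, 100.0))


SUPP_REGION = (11, 17)   # miRNA positions 12-17, 0-based half-open
SUPP_WINDOW = 18         # nt of target upstream of the site searched


def _supplementary_pairs(mirna: SequenceRecord, seq: str, site: BindingSite) -> list[tuple[str, str]]:
    """Longest contiguous complementary run (wobble allowed) between the
    miRNA 3'-supplementary region and the target upstream of the site."""
    lo, hi = SUPP_REGION
    m3 = mirna.seq[lo:min(hi, len(mirna.seq))]
    start, _ = site_span(site)
    window = seq[max(0, start - SUPP_WINDOW):start]
    if len(m3) < 2 or len(window) < 2:
        return []
    best: list[tuple[str, str]] = []
    # slide the 3' region along the upstream window; the target is
    # antiparallel, so miRNA 5'->3' reads against target 3'->5'
    rwindow = window[::-1]
    for offset in range(len(rwindow) - 1):
        run: list[tuple[str, str]] = []
        for k, mb in enumerate(m3):
            if offset + k >= len(rwindow):
                break
            tb = rwindow[offset + k]
            if _is_pair(mb, tb, wobble=True):
                run.append((mb, tb))
                if len(run) > len(best):
                    best = list(run)
            else:
                run = []
    return best


def duplex_energy(mirna: SequenceRecord, target: SequenceRecord, site: BindingSite) -> float:
    """Nearest-neighbor free energy of the seed + 3'-supplementary duplex.

    Initiation +4.09 kcal/mol, then one stacking term per adjacent pair
    step in the seed helix (positions 2-7, plus 8 for m8-type sites)
    and in the longest contiguous 3'-supplementary block.
    """
    seq = scan_sequence(target)
    core = seq[site.position:site.position + 6]
    if core != revcomp(mirna.seq[1:7]):
        raise ValueError("site does not match the given sequences")
    # seed pairs listed along the miRNA 5'->3': positions 2..7 pair
    # target positions (core end)..(core start) in reverse
    mir_side = mirna.seq[1:7]
    tgt_side = core[::-1]
    pairs = list(zip(mir_side, tgt_side))
    if site.site_type in ("7mer-m8", "8mer"):
        pairs.append((mirna.seq[7], seq[site.position - 1]))
    energy = INITIATION_KCAL
    for p1, p2 in zip(pairs, pairs[1:]):
        energy += stack_energy(p1, p2)
    supp = _supplementary_pairs(mirna, seq, site)
    for p1, p2 in zip(supp, supp[1:]):
        energy += stack_energy(p1, p2)
    return float(energy)


def _best_site(sites: list[BindingSite]) -> BindingSite:
    return min(sites, key=lambda s: (-s.score, s.energy_kcal, s.position))


def predict_pairs(mirnas: list[SequenceRecord], targets: list[SequenceRecord],
                  config) -> list[TargetPair]:
    """Predicted miRNA-target pairs passing both filters.

    A pair is retained iff its best-scoring site has score >=
    ``config.site_score_min`` and energy <= ``config.energy_max_kcal``
    (both filters, emulating a two-tool intersection).
    """
    pairs: list[TargetPair] = []
    for mir in mirnas:
        for tgt in targets:
            sites = site_scan(mir, tgt)
            if not sites:
                continue
            for s in sites:
                s.score = site_score(s, tgt)
                s.energy_kcal = duplex_energy(mir, tgt, s)
            best = _best_site(sites)
            if best.score >= config.site_score_min and best.energy_kcal <= config.energy_max_kcal:
                pairs.append(TargetPair(mir.id, tgt.id, tgt.kind, best, len(sites)))
    return pairs


def pairs_frame(pairs: list[TargetPair]):
    """Target pairs as a tabular frame for TSV export."""
    import pandas as pd

    rows = [
        (p.mirna_id, p.target_id, p.target_kind, p.best_site.site_type,
         p.best_site.position, p.best_site.score, p.best_site.energy_kcal, p.n_sites)
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=[
        "mirna_id", "target_id", "target_kind", "site_type",
        "position", "score", "energy_kcal", "n_sites",
    ])
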