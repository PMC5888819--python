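"""miRNA seed extraction, 3'UTR site scanning, and direct/indirect calls.

The seed of a mature miRNA is the 5' window starting at nucleotide 2
(1-based). Windows of 6, 7 and 8 nt are used: positions 2-7, 2-8 and 2-9.
A binding site in a 3'UTR is an exact occurrence of the DNA reverse
complement of a seed; G:U wobble pairing is not considered. An association
between a dysregulated miRNA and mRNA is called *direct* when at least one
seed site exists in the gene's 3'UTR and the regression slope is negative
(miRNA up implies mRNA down, consistent with repression through binding);
otherwise it is called *indirect* (attributable to feedback or feed-forward
regulation elsewhere in the pathway).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import AlphabetError, SpecError

SEED_LENGTHS = (6, 7, 8)
SEED_START = 1  # 0-based index of mature position 2

_RNA = set("ACGU")
_DNA = set("ACGTN")


@dataclass(frozen=True)
class SeedSet:
    """Seed windows of one mature miRNA (6/7/8-mers starting at position 2)."""

    mirna: str
    seeds: tuple[tuple[int, str, int], ...]  # (length, rna_sequence, mature_start_1based)


@dataclass(frozen=True)
class SeedMatch:
    """One seed-complementary site in a 3'UTR (0-based half-open coords)."""

    mirna: str
    gene: str
    seed_length: int
    utr_start: int
    utr_end: int


@dataclass(frozen=True)
class InteractionCall:
    gene: str
    mirna: str
    beta: float
    has_seed_match: bool
    call: str  # "direct" | "indirect"


def seed_site(seed_rna: str) -> str:
    """DNA reverse complement of an RNA seed — the UTR site it binds."""
    seed = seed_rna.upper().replace("T", "U")
    if not set(seed) <= _RNA:
        raise AlphabetError(f"non-RNA characters in seed {seed_rna!r}")
    return str(Seq(seed).back_transcribe().reverse_complement())


def extract_seeds(mirna: str, mature_rna: str) -> SeedSet:
    """Extract the 6/7/8-nt seeds of a mature miRNA sequence.

    Seeds start at mature position 2 (1-based); a length-L window requires
    the mature sequence to have at least L+1 nucleotides, so short matures
    yield a truncated seed set.
    """
    seq = mature_rna.upper().replace("T", "U")
    if not set(seq) <= _RNA:
        bad = sorted(set(seq) - _RNA)
        raise AlphabetError(f"non-RNA characters {bad} in mature sequence of {mirna}")
    seeds = tuple(
        (length, seq[SEED_START:SEED_START + length], SEED_START + 1)
        for length in SEED_LENGTHS
        if len(seq) >= SEED_START + length
    )
    return SeedSet(mirna=mirna, seeds=seeds)


def scan_utr(utr_dna: str, seed_set: SeedSet, gene: str = "") -> list[SeedMatch]:
    """Report every seed-complementary site in a UTR, overlaps included.

    The UTR must be DNA over {A,C,G,T,N}; N never matches. Coordinates are
    0-based half-open.
    """
    if not seed_set.seeds:
        raise SpecError(f"empty seed set for {seed_set.mirna}")
    utr = utr_dna.upper().replace("U", "T")
    if not set(utr) <= _DNA:
        bad = sorted(set(utr) - _DNA)
        raise AlphabetError(f"non-DNA characters {bad} in UTR of {gene or '?'}")
    matches: list[SeedMatch] = []
    for length, seed_rna, _start in seed_set.seeds:
        site = seed_site(seed_rna)
        pos = utr.find(site)
        while pos != -1:
            matches.append(SeedMatch(seed_set.mirna, gene, length, pos, pos + length))
            pos = utr.find(site, pos + 1)
    matches.sort(key=lambda m: (m.seed_length, m.utr_start))
    return matches


def scan_gene(utr_isoforms: list[str], seed_set: SeedSet, gene: str) -> list[SeedMatch]:
    """Scan every UTR isoform of a gene; a gene-level match is any isoform hit."""
    out: list[SeedMatch] = []
    for seq in utr_isoforms:
        out.extend(scan_utr(seq, seed_set, gene=gene))
    return out


def classify_interaction(gene: str, mirna: str, beta: float,
                         matches: list[SeedMatch]) -> InteractionCall:
    """Call direct iff a seed site exists and the association slope is negative."""
    has_match = len(matches) > 0
    call = "direct" if (has_match and beta < 0) else "indirect"
    return InteractionCall(gene=gene, mirna=mirna, beta=float(beta),
                           has_seed_match=has_match, call=call)


def summarize_by_mirna(calls: list[InteractionCall]) -> dict[str, dict[str, list[str]]]:
    """Partition each miRNA's associated genes by seed-match status.

    Returns ``{mirna: {"with_match": [...], "without_match": [...],
    "n_associations": int}}`` with gene lists in input order.
    """
    summary: dict[str, dict] = {}
    for call in calls:
        entry = summary.setdefault(
            call.mirna, {"with_match": [], "without_match": [], "n_associations": 0}
        )
        key = "with_match" if call.has_seed_match else "without_match"
        entry[key].append(call.gene)
        entry["n_associations"] += 1
    return summary
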