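"""Sequence-complementarity candidate filtering for plant miRNA targets.

Plant miRNAs recognise their targets through near-perfect antiparallel base
pairing.  A duplex is scored with an additive *expectation* penalty (lower is
better): mismatches, G:U wobbles and gaps each cost a fixed penalty, doubled
inside the functionally critical region (positions 2-13 from the miRNA
5' end, which spans the seed and the cleavage site).  Sites scoring at or
below a cutoff (default 2.5) are retained.  Two independent predictor outputs
are intersected to suppress false positives, and candidate pairs are finally
restricted to differentially expressed endpoints.

The penalty scheme is a reconstruction of the scoring conventions used by
plant target predictors such as psRNATarget; all penalties are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick pairs, miRNA base -> complementary target base
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
#: G:U wobble pairs tolerated at reduced penalty: (miRNA base, target base)
_WOBBLE = {("G", "U"), ("U", "G")}

MATCH = "|"
WOBBLE = ":"
MISMATCH = "."


class SequenceError(ValueError):
    """Raised for sequences outside the RNA alphabet or invalid lengths."""


@dataclass(frozen=True)
class PenaltyScheme:
    """Per-position penalties for the duplex expectation score."""

    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 2.0
    core_multiplier: float = 2.0
    core_start: int = 2   # 1-based, inclusive, from miRNA 5' end
    core_end: int = 13    # 1-based, inclusive


DEFAULT_PENALTIES = PenaltyScheme()


@dataclass
class DuplexScore:
    """Score of one miRNA/target-site duplex (ungapped)."""

    mirna_id: str
    transcript_id: str
    site_start: int          # 0-based offset on the transcript, half-open end
    expectation: float
    alignment: str           # one symbol per miRNA position, 5'->3'

    @property
    def site_end(self) -> int:
        return self.site_start + len(self.alignment)


def _check_rna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise SequenceError(f"{what} contains non-RNA characters: {sorted(bad)}")
    return seq


def duplex_expectation(
    mirna_seq: str,
    site_seq: str,
    penalties: PenaltyScheme = DEFAULT_PENALTIES,
    mirna_id: str = "miRNA",
    transcript_id: str = "site",
    site_start: int = 0,
) -> DuplexScore:
    """Expectation penalty of an ungapped miRNA/site duplex.

    Both sequences are given 5'->3'; the duplex is antiparallel, so miRNA
    position ``i`` (1-based from the 5' end) pairs with site position
    ``L - i`` (0-based).  Positions inside the core region
    (``core_start``..``core_end``) carry doubled penalties.
    """
    mirna_seq = _check_rna(mirna_seq, "miRNA")
    site_seq = _check_rna(site_seq, "site")
    if not 19 <= len(mirna_seq) <= 24:
        raise SequenceError(f"miRNA length {len(mirna_seq)} outside 19-24 nt")
    if len(site_seq) != len(mirna_seq):
        raise SequenceError("ungapped duplex requires equal lengths")
    total = 0.0
    symbols = []
    length = len(mirna_seq)
    for i, m in enumerate(mirna_seq, start=1):
        s = site_seq[length - i]
        if _COMPLEMENT[m] == s:
            symbols.append(MATCH)
            continue
        if (m, s) in _WOBBLE:
            penalty, symbol = penalties.wobble, WOBBLE
        else:
            penalty, symbol = penalties.mismatch, MISMATCH
        if penalties.core_start <= i <= penalties.core_end:
            penalty *= penalties.core_multiplier
        total += penalty
        symbols.append(symbol)
    return DuplexScore(mirna_id, transcript_id, site_start, total, "".join(symbols))


def position_penalty(
    mirna_base: str,
    site_base: str,
    position: int,
    penalties: PenaltyScheme = DEFAULT_PENALTIES,
) -> float:
    """Penalty contributed by a single miRNA position (1-based)."""
    if _COMPLEMENT[mirna_base] == site_base:
        return 0.0
    base = penalties.wobble if (mirna_base, site_base) in _WOBBLE else penalties.mismatch
    if penalties.core_start <= position <= penalties.core_end:
        base *= penalties.core_multiplier
    return base


def scan_transcript(
    mirna_seq: str,
    transcript_seq: str,
    cutoff: float = 2.5,
    penalties: PenaltyScheme = DEFAULT_PENALTIES,
    mirna_id: str = "miRNA",
    transcript_id: str = "transcript",
) -> list[DuplexScore]:
    """Ungapped sliding-window scan for target sites scoring <= ``cutoff``.

    Windows are scored on the given strand only; results are sorted by
    expectation, then position.
    """
    mirna_seq = _check_rna(mirna_seq, "miRNA")
    transcript_seq = _check_rna(transcript_seq, "transcript")
    k = len(mirna_seq)
    if len(transcript_seq) < k:
        raise SequenceError("transcript shorter than miRNA")
    hits = []
    for start in range(len(transcript_seq) - k + 1):
        score = duplex_expectation(
            mirna_seq,
            transcript_seq[start : start + k],
            penalties,
            mirna_id=mirna_id,
            transcript_id=transcript_id,
            site_start=start,
        )
        if score.expectation <= cutoff:
            hits.append(score)
    hits.sort(key=lambda h: (h.expectation, h.site_start))
    return hits


# ---------------------------------------------------------------------------
# Candidate pair sets
# ---------------------------------------------------------------------------

@dataclass
class CandidatePairSet:
    """Sequence-supported (miRNA, mRNA) pairs with predictor provenance."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair in self.pairs:
            self.provenance.setdefault(pair, frozenset())

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def add(self, mirna_id: str, mrna_id: str, source: str | None = None) -> None:
        pair = (mirna_id, mrna_id)
        self.pairs.add(pair)
        tags = set(self.provenance.get(pair, frozenset()))
        if source:
            tags.add(source)
        self.provenance[pair] = frozenset(tags)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("mirna_id\tmrna_id\tsources\n")
            for mirna, mrna in self.sorted_pairs():
                tags = ",".join(sorted(self.provenance.get((mirna, mrna), ())))
                fh.write(f"{mirna}\t{mrna}\t{tags}\n")

    @classmethod
    def from_tsv(cls, path) -> "CandidatePairSet":
        out = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            has_sources = len(header) > 2
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise SequenceError(f"{path}:{lineno}: expected >= 2 columns")
                mirna, mrna = fields[0], fields[1]
                sources = fields[2].split(",") if has_sources and len(fields) > 2 and fields[2] else []
                out.add(mirna, mrna)
                for s in sources:
                    out.add(mirna, mrna, s)
        return out


def intersect_candidates(a: CandidatePairSet, b: CandidatePairSet) -> CandidatePairSet:
    """Pairs predicted by both sources; provenance records both tags."""
    out = CandidatePairSet()
    for pair in a.pairs & b.pairs:
        out.pairs.add(pair)
        out.provenance[pair] = a.provenance.get(pair, frozenset()) | b.provenance.get(
            pair, frozenset()
        )
    return out


def restrict_to_de(
    candidates: CandidatePairSet,
    de_mirnas,
    de_mrnas,
) -> CandidatePairSet:
    """Keep candidate pairs whose both endpoints are differentially expressed."""
    mirnas = set(de_mirnas)
    mrnas = set(de_mrnas)
    out = CandidatePairSet()
    for mirna, mrna in candidates.pairs:
        if mirna in mirnas and mrna in mrnas:
            out.pairs.add((mirna, mrna))
            out.provenance[(mirna, mrna)] = candidates.provenance.get(
                (mirna, mrna), frozenset()
            )
    return out
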