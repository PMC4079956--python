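"""Reference sequence sets and assay-to-reference identifier maps.

miRNA references follow the miRBase convention: a short "mature" sequence
excised from a longer hairpin "precursor".  Catalogued sequences are RNA
(``U``), sequencer output is DNA (``T``); every sequence entering the
package is first canonicalized to an uppercase DNA alphabet so that all
downstream matching is a plain string comparison.

qPCR assay panels are designed against a historical catalogue version, so
assay identifiers are reconciled to current identifiers by exact mature
*sequence* match against an ordered list of species tiers (rat first, then
mouse, then human by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_CANON = str.maketrans("acgtunACGTUN", "ACGTTNACGTTN")
_ALLOWED = set("acgtunACGTUN")


class MalformedSequenceError(ValueError):
    """A sequence contains a character outside the IUPAC {A,C,G,T,U,N} subset."""


def canonicalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA ``U`` to DNA ``T``.

    ``N`` is preserved (and never matches anything downstream).  Any other
    character raises :class:`MalformedSequenceError` naming its position.
    """
    if not seq:
        raise MalformedSequenceError("empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in _ALLOWED:
            raise MalformedSequenceError(
                f"invalid character {ch!r} at position {pos + 1}"
            )
    return seq.translate(_CANON)


@dataclass(frozen=True)
class MiRNARecord:
    """One mature miRNA, optionally linked to its hairpin precursor.

    Invariant: ``mature_seq`` is canonical DNA and, when a precursor is
    present, a contiguous substring of ``precursor_seq``.
    """

    mirna_id: str
    species: str
    mature_seq: str
    precursor_id: str | None = None
    precursor_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.mature_seq:
            raise ValueError(f"{self.mirna_id}: empty mature sequence")
        if self.precursor_seq is not None and self.mature_seq not in self.precursor_seq:
            raise ValueError(
                f"{self.mirna_id}: mature sequence is not a substring of "
                f"precursor {self.precursor_id}"
            )


class ReferenceTier:
    """One species' worth of mature (+precursor) records with exact lookup."""

    def __init__(self, species: str, records: list[MiRNARecord]):
        for rec in records:
            if rec.species != species:
                raise ValueError(
                    f"record {rec.mirna_id} has species {rec.species!r}, "
                    f"tier is {species!r}"
                )
        self.species = species
        self.records: list[MiRNARecord] = list(records)
        self.by_id: dict[str, MiRNARecord] = {}
        self.by_seq: dict[str, list[str]] = {}
        for rec in records:
            if rec.mirna_id in self.by_id:
                raise ValueError(f"duplicate mature id {rec.mirna_id}")
            self.by_id[rec.mirna_id] = rec
            self.by_seq.setdefault(rec.mature_seq, []).append(rec.mirna_id)
        for ids in self.by_seq.values():
            ids.sort()

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, seq: str) -> list[str]:
        """Exact mature-sequence lookup; returns matching ids (sorted)."""
        return self.by_seq.get(seq, [])


@dataclass
class SequenceDB:
    """A named set of auxiliary reference sequences (other-ncRNA, exon,
    dietary genomes ...) matched by exact substring containment."""

    name: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {
            name: canonicalize_sequence(seq) for name, seq in self.sequences.items()
        }

    def contains(self, read_seq: str) -> str | None:
        """Name of the first DB sequence (sorted by name) containing the read."""
        if "N" in read_seq:
            return None
        for name in sorted(self.sequences):
            if read_seq in self.sequences[name]:
                return name
        return None


@dataclass
class IDMap:
    """Assay-id -> canonical-id reconciliation by exact mature sequence.

    Unmapped assay ids are carried explicitly, never silently dropped.
    """

    mapped: dict[str, str]
    unmapped: list[str]
    sequences: dict[str, str] = field(default_factory=dict)

    def translate(self, assay_id: str) -> str | None:
        return self.mapped.get(assay_id)


def _fasta_id(header_id: str) -> str:
    # first whitespace-delimited token only
    return header_id.split()[0]


def load_fasta_sequences(path) -> dict[str, str]:
    """Load a FASTA file into an id -> canonical-sequence dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = _fasta_id(rec.id)
        if rid in out:
            raise ValueError(f"duplicate FASTA id {rid} in {path}")
        out[rid] = canonicalize_sequence(str(rec.seq))
    return out


def load_sequence_db(path, name: str) -> SequenceDB:
    return SequenceDB(name=name, sequences=load_fasta_sequences(path))


def default_precursor_id(mature_id: str) -> str:
    """Default linkage rule: mature id with a trailing -5p/-3p arm suffix
    stripped equals the precursor id."""
    for suffix in ("-5p", "-3p"):
        if mature_id.endswith(suffix):
            return mature_id[: -len(suffix)]
    return mature_id


def load_mirna_reference(
    mature_path,
    precursor_path=None,
    species: str = "rat",
    precursor_map: dict[str, str] | None = None,
) -> ReferenceTier:
    """Build a :class:`ReferenceTier` from mature (and optional precursor) FASTA.

    Precursor linkage uses an explicit ``precursor_map`` (mature id ->
    precursor id) when given, else the arm-suffix-stripping default.  A
    linked precursor that does not contain the mature sequence drops the
    link with a warning; the mature record is kept.
    """
    matures = load_fasta_sequences(mature_path)
    precursors = load_fasta_sequences(precursor_path) if precursor_path else {}
    records = []
    for mid, mseq in matures.items():
        pid = (precursor_map or {}).get(mid, default_precursor_id(mid))
        pseq = precursors.get(pid)
        if pseq is not None and mseq not in pseq:
            logger.warning(
                "%s: mature sequence not found in precursor %s; link dropped",
                mid,
                pid,
            )
            pid, pseq = None, None
        elif pseq is None:
            pid = None
        records.append(
            MiRNARecord(
                mirna_id=mid,
                species=species,
                mature_seq=mseq,
                precursor_id=pid,
                precursor_seq=pseq,
            )
        )
    logger.info("loaded %d mature miRNAs for %s from %s", len(records), species, mature_path)
    return ReferenceTier(species=species, records=records)


def write_reference(tier: ReferenceTier, mature_path, precursor_path=None) -> None:
    """Write a tier back to FASTA (round-trips with :func:`load_mirna_reference`)."""
    mature_recs = [
        SeqRecord(Seq(rec.mature_seq), id=rec.mirna_id, description="")
        for rec in tier.records
    ]
    SeqIO.write(mature_recs, str(mature_path), "fasta")
    if precursor_path is not None:
        seen: dict[str, str] = {}
        for rec in tier.records:
            if rec.precursor_id is not None:
                seen.setdefault(rec.precursor_id, rec.precursor_seq)
        prec_recs = [
            SeqRecord(Seq(seq), id=pid, description="") for pid, seq in seen.items()
        ]
        SeqIO.write(prec_recs, str(precursor_path), "fasta")


def write_sequence_db(db: SequenceDB, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(db.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def load_assay_table(path) -> list[tuple[str, str]]:
    """Two-column TSV (assay_id, sequence); a leading header row is allowed."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i + 1}: expected two tab-separated columns")
            if i == 0 and parts[0].lower() in {"assay_id", "id"}:
                continue
            rows.append((parts[0], parts[1]))
    return rows


def build_id_map(
    assay_table: list[tuple[str, str]], tier_list: list[ReferenceTier]
) -> IDMap:
    """Map each assay id to the first tier (in order) with an exact mature match.

    Two same-tier records sharing the sequence resolve lexicographically by
    canonical id with a warning.  Assays matching nowhere land in
    ``unmapped``.
    """
    if not assay_table:
        raise ValueError("empty assay table")
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    sequences: dict[str, str] = {}
    for assay_id, raw_seq in assay_table:
        seq = canonicalize_sequence(raw_seq)
        if assay_id in sequences:
            raise ValueError(f"duplicate assay id {assay_id}")
        sequences[assay_id] = seq
        hit = None
        for tier in tier_list:
            ids = tier.lookup(seq)
            if ids:
                if len(ids) > 1:
                    logger.warning(
                        "assay %s matches %d records in %s tier; choosing %s",
                        assay_id,
                        len(ids),
                        tier.species,
                        ids[0],
                    )
                hit = ids[0]
                break
        if hit is None:
            unmapped.append(assay_id)
        else:
            mapped[assay_id] = hit
    return IDMap(mapped=mapped, unmapped=unmapped, sequences=sequences)
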