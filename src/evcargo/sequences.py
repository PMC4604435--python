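"""RNA/DNA sequence primitives and the packaged RNY5 oligonucleotide set.

All coordinates in this package are 1-based closed intervals, matching the
"nucleotides 14--21" convention used when describing the processing motif.
RNA sequences use {A,C,G,U}; DNA probes use {A,C,G,T} and are flagged with
``is_dna``.  Mixed alphabets are rejected at construction time.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Sequence residues do not match the declared alphabet."""


class FragmentNotFoundError(LookupError):
    """A fragment is not a substring of its putative source transcript."""


@dataclass(frozen=True)
class RnaSeq:
    """A validated RNA (or DNA, when ``is_dna``) sequence.

    Parameters
    ----------
    id:
        Short label, e.g. ``"RNY5_31mer"``.
    residues:
        Residue string over {A,C,G,U} (RNA) or {A,C,G,T} (DNA).
    is_dna:
        True for DNA oligos such as hybridization probes.
    """

    id: str
    residues: str
    is_dna: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"{self.id}: empty sequence")
        alphabet = DNA_ALPHABET if self.is_dna else RNA_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            kind = "DNA" if self.is_dna else "RNA"
            raise AlphabetError(
                f"{self.id}: residues {sorted(bad)} not in {kind} alphabet"
            )

    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # convenience alias
        return len(self.residues)

    def slice(self, start_1based: int, end_1based: int, new_id: str | None = None) -> "RnaSeq":
        """Closed-interval 1-based slice."""
        _check_range(self, start_1based, end_1based)
        return RnaSeq(
            new_id or f"{self.id}[{start_1based}-{end_1based}]",
            self.residues[start_1based - 1 : end_1based],
            self.is_dna,
        )

    def reverse_complement(self, new_id: str | None = None) -> "RnaSeq":
        table = _DNA_COMPLEMENT if self.is_dna else _RNA_COMPLEMENT
        return RnaSeq(
            new_id or f"{self.id}_rc", self.residues.translate(table)[::-1], self.is_dna
        )


@dataclass(frozen=True)
class MotifSpec:
    """A motif with its location on the reference transcript."""

    sequence: str
    start_1based: int
    end_1based: int

    def __post_init__(self) -> None:
        if self.end_1based - self.start_1based + 1 != len(self.sequence):
            raise ValueError("motif span does not match motif length")


#: The single-stranded 8-nt processing motif in the upper stem of the Y RNA,
#: at transcript positions 14-21 of the 83-nt primary transcript.
PROCESSING_MOTIF = MotifSpec("GUUGUGGG", 14, 21)

# --------------------------------------------------------------------------
# The packaged oligonucleotide set (printed synthetic oligos, "r"-prefix
# notation normalized to plain residues) plus the Northern probe (DNA).
# --------------------------------------------------------------------------

RNY5_83MER = RnaSeq(
    "RNY5_83mer",
    "AGUUGGUCCGAGUGUUGUGGGUUAUUGUUAAGUUGAUUUAACAUUGUCUCC"
    "CCCCACAACCGCGCUUGACUAGCUUGCUGUUU",
)
RNY5_31MER = RnaSeq("RNY5_31mer", "AGUUGGUCCGAGUGUUGUGGGUUAUUGUUAA")
RNY5_23MER = RnaSeq("RNY5_23mer", "AGUUGGUCCGAGUGUUGUGGGUU")
RNY5_31MER_SCRAMBLED = RnaSeq(
    "RNY5_31mer_scrambled", "UGGUGCGUGUUGUUUAGAUUAAGUGGUUGAC"
)
RNY5_MOTIF_DELETED = RnaSeq("RNY5_motif_deleted", "AGUUGGUCCGAGUUUAUUGUUAA")
RNY5_MOTIF_SCRAMBLED = RnaSeq(
    "RNY5_motif_scrambled", "AGUUGGUCCGAGUACGUACAGUUAUUGUUAA"
)
RNY5_3P_32MER = RnaSeq("RNY5_3p_32mer", "CCCCACAACCGCGCUUGACUAGCUUGCUGUUU")
# The double-stranded 31-mer duplex as synthesized: the sense strand carries
# one extra 3' G over the plain 31-mer; the antisense strand is the 3'-side
# 32-mer.
RNY5_DS_SENSE = RnaSeq("RNY5_ds_sense", "AGUUGGUCCGAGUGUUGUGGGUUAUUGUUAAG")
RNY5_DS_ANTISENSE = RnaSeq("RNY5_ds_antisense", RNY5_3P_32MER.residues)
NORTHERN_PROBE = RnaSeq(
    "RNY5_northern_probe", "CTTAACAATAACCCACAACACTCGGACCAACT", is_dna=True
)

OLIGOS: dict[str, RnaSeq] = {
    s.id: s
    for s in (
        RNY5_83MER,
        RNY5_31MER,
        RNY5_23MER,
        RNY5_31MER_SCRAMBLED,
        RNY5_MOTIF_DELETED,
        RNY5_MOTIF_SCRAMBLED,
        RNY5_3P_32MER,
        RNY5_DS_SENSE,
        RNY5_DS_ANTISENSE,
    )
}


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def _check_same_alphabet(a: RnaSeq, b_residues: str, b_is_dna: bool) -> None:
    if a.is_dna != b_is_dna:
        raise AlphabetError("mixed RNA/DNA operands")


def _check_range(seq: RnaSeq, start: int, end: int) -> None:
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(
            f"range {start}-{end} out of bounds for {seq.id} (length {len(seq)})"
        )


def find_motif(seq: RnaSeq, motif: str) -> list[int]:
    """All 1-based start positions at which ``motif`` occurs in ``seq``.

    Overlapping occurrences are all reported; the list is sorted ascending
    and empty when the motif is absent.
    """
    if not motif:
        raise ValueError("empty motif")
    alphabet = DNA_ALPHABET if seq.is_dna else RNA_ALPHABET
    if set(motif) - alphabet:
        raise AlphabetError(f"motif {motif!r} not in sequence alphabet")
    hits = []
    pos = seq.residues.find(motif)
    while pos != -1:
        hits.append(pos + 1)
        pos = seq.residues.find(motif, pos + 1)
    return hits


def locate_fragment(fragment: RnaSeq, reference: RnaSeq) -> int:
    """Smallest 1-based offset at which ``fragment`` occurs exactly in
    ``reference``; raises :class:`FragmentNotFoundError` when absent."""
    _check_same_alphabet(reference, fragment.residues, fragment.is_dna)
    if len(fragment) > len(reference):
        raise FragmentNotFoundError(
            f"{fragment.id} longer than reference {reference.id}"
        )
    pos = reference.residues.find(fragment.residues)
    if pos == -1:
        raise FragmentNotFoundError(f"{fragment.id} not found in {reference.id}")
    return pos + 1


def perturb(
    seq: RnaSeq,
    action: str,
    start_1based: int | None = None,
    end_1based: int | None = None,
    replacement: str | None = None,
    seed: int | None = None,
    new_id: str | None = None,
) -> RnaSeq:
    """Sequence perturbations used to build the oligo variant panel.

    ``delete_range`` removes the closed interval; ``replace_range``
    substitutes ``replacement`` in place of it; ``shuffle_all`` returns a
    seeded permutation of the residues (composition preserved).
    """
    if action == "shuffle_all":
        rng = random.Random(seed)
        residues = list(seq.residues)
        rng.shuffle(residues)
        return RnaSeq(new_id or f"{seq.id}_shuffled", "".join(residues), seq.is_dna)

    if start_1based is None or end_1based is None:
        raise ValueError(f"{action} requires a range")
    _check_range(seq, start_1based, end_1based)
    head = seq.residues[: start_1based - 1]
    tail = seq.residues[end_1based:]
    if action == "delete_range":
        return RnaSeq(new_id or f"{seq.id}_del", head + tail, seq.is_dna)
    if action == "replace_range":
        if replacement is None:
            raise ValueError("replace_range requires a replacement")
        _check_same_alphabet(seq, replacement, seq.is_dna)
        alphabet = DNA_ALPHABET if seq.is_dna else RNA_ALPHABET
        if set(replacement) - alphabet:
            raise AlphabetError("replacement not in sequence alphabet")
        return RnaSeq(new_id or f"{seq.id}_repl", head + replacement + tail, seq.is_dna)
    raise ValueError(f"unknown perturbation {action!r}")


def probe_complementarity(probe: RnaSeq, target: RnaSeq) -> tuple[int, int] | None:
    """1-based span on ``target`` (RNA) whose reverse complement equals the
    DNA ``probe`` (T/U mapped), or None when the probe does not hybridize."""
    if not probe.is_dna:
        raise AlphabetError("probe must be DNA")
    if target.is_dna:
        raise AlphabetError("target must be RNA")
    # reverse-complement the probe into RNA space and search the target
    rc = probe.residues.translate(_DNA_COMPLEMENT)[::-1].replace("T", "U")
    pos = target.residues.find(rc)
    if pos == -1:
        return None
    return (pos + 1, pos + len(rc))


def composition(seq: RnaSeq) -> dict[str, int]:
    """Residue -> count map; counts sum to the sequence length."""
    return dict(Counter(seq.residues))


# --------------------------------------------------------------------------
# FASTA plumbing for the packaged oligo set
# --------------------------------------------------------------------------


def write_oligo_fasta(path: str | Path, oligos: Iterable[RnaSeq] | None = None) -> None:
    records = [
        SeqRecord(Seq(o.residues), id=o.id, description="")
        for o in (oligos if oligos is not None else OLIGOS.values())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_oligo_fasta(path: str | Path, is_dna: bool = False) -> dict[str, RnaSeq]:
    out: dict[str, RnaSeq] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = RnaSeq(rec.id, str(rec.seq), is_dna=is_dna)
    return out
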