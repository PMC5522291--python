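"""Window extraction and benchmark assembly for candidate m5C sites.

A candidate site is a cytosine with xi flanking nucleotides on each side,
giving a (2*xi + 1)-nt window with C fixed at the center.  Sequences arrive
as DNA or RNA FASTA (T is converted to U), site annotations as a TSV of
(seq_id, 1-based position, label).  Windows near sequence ends are completed
by replicating the terminal residue (the missing position's nearest existing
neighbour).  Within each label subset, exact duplicate window strings are
removed, keeping the first occurrence; the same string may appear once in
each subset.

Coordinates are 1-based and inclusive throughout; the window center is index
xi + 1 (1-based).  Windows overlapping any non-ACGU symbol (N and other
ambiguity codes are tolerated on input but carry no usable composition) are
excluded from benchmarks and counted in the build log.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
#: IUPAC ambiguity codes tolerated (flagged, excluded from windows)
AMBIGUITY = frozenset("NRYSWKMBDHV")

POSITIVE = "pos"
NEGATIVE = "neg"
DEFAULT_XI = 20


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence (uppercase, T already converted to U)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"empty sequence record {self.id!r}")
        bad = set(self.residues) - RNA_ALPHABET - AMBIGUITY
        if bad:
            raise InputError(f"sequence {self.id!r} has unrecognized symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ambiguous_positions(self) -> tuple[int, ...]:
        """1-based positions of non-ACGU symbols."""
        return tuple(i + 1 for i, c in enumerate(self.residues) if c not in RNA_ALPHABET)


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated cytosine: sequence id, 1-based position, class label."""

    seq_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise InputError(f"label must be '{POSITIVE}' or '{NEGATIVE}', got {self.label!r}")
        if self.position < 1:
            raise InputError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class LabeledWindow:
    """A (2*xi+1)-nt window centered on C, with label and provenance."""

    window: str
    xi: int
    label: str
    seq_id: str = ""
    position: int = 0

    def __post_init__(self) -> None:
        if len(self.window) != 2 * self.xi + 1:
            raise InputError(
                f"window length {len(self.window)} != 2*xi+1 = {2 * self.xi + 1}"
            )
        if self.window[self.xi] != "C":
            raise InputError(f"window center is {self.window[self.xi]!r}, not C")


@dataclass
class BenchmarkDataset:
    """Deduplicated positive and negative window subsets sharing one xi."""

    positives: list[LabeledWindow]
    negatives: list[LabeledWindow]
    xi: int

    def __post_init__(self) -> None:
        for subset, name in ((self.positives, "positive"), (self.negatives, "negative")):
            seen: set[str] = set()
            for w in subset:
                if w.xi != self.xi:
                    raise InputError(f"{name} window xi={w.xi} != dataset xi={self.xi}")
                if w.window in seen:
                    raise InputError(f"duplicate window string within the {name} subset")
                seen.add(w.window)

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)

    @property
    def windows(self) -> list[LabeledWindow]:
        """Positives (input order) then negatives."""
        return list(self.positives) + list(self.negatives)


def dna_to_rna(raw: str, id: str = "") -> RnaSequence:
    """Normalize a raw DNA/RNA string: uppercase, T -> U.

    Idempotent and length-preserving.  IUPAC ambiguity symbols are kept and
    surface later through :attr:`RnaSequence.ambiguous_positions`.
    """
    if not raw:
        raise InputError(f"empty sequence record {id!r}")
    return RnaSequence(id=id, residues=raw.upper().replace("T", "U"))


def scan_c_sites(seq: RnaSequence) -> list[int]:
    """All 1-based positions of C residues, ascending."""
    return [i + 1 for i, c in enumerate(seq.residues) if c == "C"]


def extract_window(seq: RnaSequence, position: int, xi: int = DEFAULT_XI) -> str:
    """The (2*xi+1)-nt window centered on the C at ``position`` (1-based).

    Flank positions before the sequence start are filled with the first
    residue, positions past the end with the last residue.
    """
    if xi < 1:
        raise InputError(f"xi must be >= 1, got {xi}")
    if not 1 <= position <= len(seq):
        raise InputError(
            f"position {position} outside sequence {seq.id!r} of length {len(seq)}"
        )
    if seq.residues[position - 1] != "C":
        raise InputError(
            f"misannotation: residue at {seq.id!r}:{position} is "
            f"{seq.residues[position - 1]!r}, not C"
        )
    left = max(0, xi - (position - 1))
    right = max(0, position + xi - len(seq))
    core = seq.residues[max(0, position - 1 - xi) : position + xi]
    return seq.residues[0] * left + core + seq.residues[-1] * right


def build_benchmark(
    seqs: Iterable[RnaSequence],
    annotations: Iterable[SiteAnnotation],
    xi: int = DEFAULT_XI,
) -> BenchmarkDataset:
    """Extract, filter and deduplicate windows into a benchmark dataset.

    Exact duplicate window strings are dropped within each label subset
    (first occurrence kept, input order); a string present in both subsets is
    retained in both.  Windows containing any non-ACGU symbol are excluded
    and logged.  Annotations referencing unknown sequences raise, listing
    every offending record.
    """
    by_id = {s.id: s for s in seqs}
    annotations = list(annotations)
    unknown = [a for a in annotations if a.seq_id not in by_id]
    if unknown:
        raise InputError(
            "annotations reference unknown sequence ids: "
            + ", ".join(f"{a.seq_id}:{a.position}" for a in unknown)
        )
    subsets: dict[str, list[LabeledWindow]] = {POSITIVE: [], NEGATIVE: []}
    seen: dict[str, set[str]] = {POSITIVE: set(), NEGATIVE: set()}
    n_ambiguous = n_duplicate = 0
    for ann in annotations:
        w = extract_window(by_id[ann.seq_id], ann.position, xi)
        if set(w) - RNA_ALPHABET:
            n_ambiguous += 1
            continue
        if w in seen[ann.label]:
            n_duplicate += 1
            continue
        seen[ann.label].add(w)
        subsets[ann.label].append(
            LabeledWindow(window=w, xi=xi, label=ann.label, seq_id=ann.seq_id, position=ann.position)
        )
    logger.info(
        "benchmark built: %d positive, %d negative windows (%d duplicates removed, "
        "%d windows with ambiguity symbols excluded)",
        len(subsets[POSITIVE]), len(subsets[NEGATIVE]), n_duplicate, n_ambiguous,
    )
    return BenchmarkDataset(positives=subsets[POSITIVE], negatives=subsets[NEGATIVE], xi=xi)


def subsample_negatives(dataset: BenchmarkDataset, ratio: float, seed: int) -> BenchmarkDataset:
    """Downsample negatives to ``ratio`` negatives per positive (seeded).

    Mirrors the benchmark's 1:3 class ratio when building from genome-scale
    input where every non-annotated C is a negative candidate.  A no-op when
    the dataset already has fewer negatives than the target.
    """
    if ratio <= 0:
        raise InputError(f"ratio must be positive, got {ratio}")
    target = int(round(ratio * len(dataset.positives)))
    if target >= len(dataset.negatives):
        return dataset
    rng = random.Random(seed)
    keep = sorted(rng.sample(range(len(dataset.negatives)), target))
    return BenchmarkDataset(
        positives=list(dataset.positives),
        negatives=[dataset.negatives[i] for i in keep],
        xi=dataset.xi,
    )


# ---------------------------------------------------------------------------
# IO


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read sequences from FASTA, converting DNA to RNA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return [dna_to_rna(str(r.seq), id=r.id) for r in records]


def write_fasta(windows: Sequence[LabeledWindow], path: str | Path) -> None:
    """Write windows as FASTA, label and provenance encoded in the header."""
    records = []
    for i, w in enumerate(windows):
        name = f"win{i + 1}|label={w.label}|src={w.seq_id}:{w.position}"
        records.append(SeqRecord(Seq(w.window), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_windows_fasta(path: str | Path, xi: int) -> list[LabeledWindow]:
    """Read back windows written by :func:`write_fasta`."""
    out = []
    for lineno, rec in enumerate(SeqIO.parse(str(path), "fasta"), 1):
        fields = dict(
            part.split("=", 1) for part in rec.id.split("|")[1:] if "=" in part
        )
        if "label" not in fields:
            raise InputError(f"record {lineno} in {path}: missing |label= tag in header")
        src_id, _, src_pos = fields.get("src", ":0").rpartition(":")
        out.append(
            LabeledWindow(
                window=str(rec.seq).upper().replace("T", "U"),
                xi=xi,
                label=fields["label"],
                seq_id=src_id,
                position=int(src_pos or 0),
            )
        )
    if not out:
        raise InputError(f"no FASTA records found in {path}")
    return out


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read the site annotation TSV (columns seq_id, position, label)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"seq_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read annotations {path}: {exc}") from exc
    required = {"seq_id", "position", "label"}
    if not required.issubset(df.columns):
        raise InputError(f"annotation file {path} must have columns {sorted(required)}")
    out = []
    for row in df.itertuples():
        try:
            out.append(SiteAnnotation(str(row.seq_id), int(row.position), str(row.label)))
        except (InputError, ValueError) as exc:
            raise InputError(f"{path} line {row.Index + 2}: {exc}") from exc
    return out


def write_benchmark(dataset: BenchmarkDataset, path: str | Path) -> None:
    """Write a benchmark as TSV (columns window, label, seq_id, position)."""
    rows = [
        {"window": w.window, "label": w.label, "seq_id": w.seq_id, "position": w.position}
        for w in dataset.windows
    ]
    pd.DataFrame(rows, columns=["window", "label", "seq_id", "position"]).to_csv(
        path, sep="\t", index=False
    )


def read_benchmark(path: str | Path) -> BenchmarkDataset:
    """Read a benchmark TSV written by :func:`write_benchmark`."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"seq_id": str}, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read benchmark {path}: {exc}") from exc
    required = {"window", "label"}
    if not required.issubset(df.columns):
        raise InputError(f"benchmark file {path} must have columns {sorted(required)}")
    if df.empty:
        raise InputError(f"benchmark file {path} has no rows")
    lengths = df["window"].str.len().unique()
    if len(lengths) != 1 or lengths[0] % 2 == 0:
        raise InputError(f"benchmark windows must share one odd length, got {sorted(lengths)}")
    xi = (int(lengths[0]) - 1) // 2
    subsets: dict[str, list[LabeledWindow]] = {POSITIVE: [], NEGATIVE: []}
    for row in df.itertuples():
        try:
            w = LabeledWindow(
                window=str(row.window),
                xi=xi,
                label=str(row.label),
                seq_id=str(getattr(row, "seq_id", "")),
                position=int(getattr(row, "position", 0) or 0),
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"{path} line {row.Index + 2}: {exc}") from exc
        subsets[w.label].append(w)
    return BenchmarkDataset(positives=subsets[POSITIVE], negatives=subsets[NEGATIVE], xi=xi)
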