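"""Reading, labeling and curating locus alignments.

A locus is a multi-FASTA file of equal-length haploid sequences; population
labels come from a separate two-column TSV (sample_id, population). Before
any statistic is computed the alignment passes the study's curation gates:
individuals missing more than 20% of the alignment are dropped, and a locus
is analyzed only with at least 15 sequences and at least 5 per population.

Bases are normalized to upper case; ``-`` and ``N`` both count as missing,
for masking and for the missingness rule alike.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = ord("-")
AMBIG = ord("N")

#: characters treated as missing data everywhere in the package
MISSING_CHARS = frozenset("-N")


def _missing_matrix(arr: np.ndarray) -> np.ndarray:
    """Boolean (n, L) matrix of missing cells ('-' or 'N')."""
    return (arr == GAP) | (arr == AMBIG)


@dataclass(frozen=True)
class LabeledAlignment:
    """Equal-length sequences with optional per-sample population labels.

    ``seq_array`` holds the alignment as a (n, L) uint8 matrix of ASCII
    codes (upper case). ``populations[i]`` is ``None`` until
    :func:`assign_populations` attaches labels.
    """

    locus_id: str
    sample_ids: tuple[str, ...]
    populations: tuple[str | None, ...]
    seq_array: np.ndarray

    def __post_init__(self) -> None:
        if self.seq_array.ndim != 2 or self.seq_array.shape[0] == 0:
            raise ValueError("no sequences")
        if len(self.sample_ids) != self.seq_array.shape[0]:
            raise ValueError("sample_ids and sequences disagree in count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("populations and sequences disagree in count")

    # -- basic views ------------------------------------------------------

    @property
    def n(self) -> int:
        return self.seq_array.shape[0]

    @property
    def length(self) -> int:
        return self.seq_array.shape[1]

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(row.tobytes().decode("ascii") for row in self.seq_array)

    def population_set(self) -> tuple[str, ...]:
        """Distinct population labels, sorted; excludes unlabeled samples."""
        return tuple(sorted({p for p in self.populations if p is not None}))

    def population_indices(self, population: str) -> np.ndarray:
        return np.flatnonzero(np.array([p == population for p in self.populations]))

    def population_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.populations:
            if p is not None:
                counts[p] = counts.get(p, 0) + 1
        return counts

    def subset(self, indices: Sequence[int]) -> "LabeledAlignment":
        idx = np.asarray(indices, dtype=int)
        return LabeledAlignment(
            locus_id=self.locus_id,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            populations=tuple(self.populations[i] for i in idx),
            seq_array=self.seq_array[idx].copy(),
        )

    def missing_fractions(self) -> np.ndarray:
        """Per-sample fraction of columns that are '-' or 'N'."""
        return _missing_matrix(self.seq_array).mean(axis=1)


@dataclass(frozen=True)
class SiteMask:
    """Columns retained for analysis, 0-based.

    ``complete`` (listwise) deletion keeps only columns with no missing
    character in any sequence; ``pairwise`` keeps every column and defers
    exclusion to each sequence pair.
    """

    kept_columns: np.ndarray
    deletion_mode: str

    @property
    def n_sites(self) -> int:
        return int(len(self.kept_columns))


def alignment_from_sequences(
    sequences: Iterable[str],
    sample_ids: Sequence[str] | None = None,
    populations: Sequence[str | None] | None = None,
    locus_id: str = "locus",
) -> LabeledAlignment:
    """Build an alignment from in-memory strings (test and simulator entry)."""
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("unequal sequence lengths")
    if sample_ids is None:
        sample_ids = tuple(f"s{i + 1}" for i in range(len(seqs)))
    if populations is None:
        populations = tuple(None for _ in seqs)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(seqs), lengths.pop()).copy()
    return LabeledAlignment(locus_id, tuple(sample_ids), tuple(populations), arr)


def read_alignment(path: str | Path, locus_id: str | None = None) -> LabeledAlignment:
    """Read a multi-FASTA alignment; populations are unlabeled.

    Raises ``ValueError("unequal sequence lengths")`` on a ragged file and
    ``ValueError("no sequences")`` on an empty one.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return alignment_from_sequences(
        [str(r.seq) for r in records],
        sample_ids=[r.id for r in records],
        locus_id=locus_id if locus_id is not None else path.stem,
    )


def write_alignment(aln: LabeledAlignment, path: str | Path) -> None:
    """Write the alignment as FASTA, preserving sample order."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


_POPMAP_HEADERS = {"sample", "sample_id", "id", "name"}


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV sample→population map; header row optional."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"population map line {lineno + 1}: need 2 columns")
            sid, pop = fields[0].strip(), fields[1].strip()
            if lineno == 0 and sid.lower() in _POPMAP_HEADERS:
                continue
            mapping[sid] = pop
    if not mapping:
        raise ValueError("empty population map")
    return mapping


def write_popmap(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, pop in mapping.items():
            fh.write(f"{sid}\t{pop}\n")


def assign_populations(
    aln: LabeledAlignment, popmap: Mapping[str, str]
) -> LabeledAlignment:
    """Attach population labels; every sample must appear in the map."""
    missing = [sid for sid in aln.sample_ids if sid not in popmap]
    if missing:
        raise ValueError(
            f"sample missing from population map: {', '.join(missing)}"
        )
    return replace(aln, populations=tuple(popmap[sid] for sid in aln.sample_ids))


def filter_missingness(
    aln: LabeledAlignment,
    max_missing_fraction: float = 0.20,
    log: bool = False,
) -> tuple[LabeledAlignment, list[str]]:
    """Drop samples missing strictly more than ``max_missing_fraction``.

    The rule is strict (">20%"): a sample at exactly the threshold is kept.
    Returns the filtered alignment and the dropped sample ids, preserving
    sample order.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    frac = aln.missing_fractions()
    keep = np.flatnonzero(frac <= max_missing_fraction)
    dropped = [aln.sample_ids[i] for i in np.flatnonzero(frac > max_missing_fraction)]
    if log:
        for sid in dropped:
            print(f"[popdiv] {aln.locus_id}: dropped {sid} (missing > "
                  f"{max_missing_fraction:.0%})", file=sys.stderr)
    if len(keep) == 0:
        raise ValueError("empty alignment after missingness filter")
    if len(keep) == aln.n:
        return aln, []
    return aln.subset(keep), dropped


def check_eligibility(
    aln: LabeledAlignment, min_total: int = 15, min_per_pop: int = 5
) -> tuple[bool, str]:
    """Locus eligibility gate: total and per-population sample minimums."""
    counts = aln.population_counts()
    if any(p is None for p in aln.populations):
        return False, "unlabeled samples present"
    small = [p for p, c in counts.items() if c < min_per_pop]
    if small:
        return False, (
            f"population below minimum ({', '.join(sorted(small))} < {min_per_pop})"
        )
    total = sum(counts.values())
    if total < min_total:
        return False, f"total below minimum ({total} < {min_total})"
    return True, "eligible"


def build_site_mask(
    aln: LabeledAlignment, deletion_mode: str = "complete"
) -> SiteMask:
    """Columns analyzed under the chosen deletion convention."""
    if deletion_mode not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion mode: {deletion_mode}")
    if deletion_mode == "complete":
        kept = np.flatnonzero(~_missing_matrix(aln.seq_array).any(axis=0))
    else:
        kept = np.arange(aln.length)
    return SiteMask(kept_columns=kept, deletion_mode=deletion_mode)
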