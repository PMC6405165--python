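"""Codon adaptation index and codon-usage-driven back-translation.

The codon adaptation index (CAI, Sharp & Li) scores how closely a coding
sequence follows a species' codon usage: each codon's relative
adaptiveness ``w`` is its usage frequency divided by the most-used
synonymous codon's frequency, and the CAI is the geometric mean of ``w``
over the sequence (computed in the log domain; single-codon families and
stops excluded by default). "Codon averaging" is the inverse operation:
back-translating a protein by choosing, per residue, either the species'
most frequent codon or a codon sampled from the within-family usage
frequencies.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .errors import SequenceError, TableError

_STANDARD = unambiguous_dna_by_id[1]

#: amino acid (one letter; '*' for stop) -> tuple of synonymous DNA codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)
SYNONYMOUS_FAMILIES["*"] = tuple(sorted(_STANDARD.stop_codons))

CODON_TO_AA: dict[str, str] = {c: aa for aa, codons in SYNONYMOUS_FAMILIES.items()
                               for c in codons}
ALL_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: Codons excluded from the CAI by default: the single-codon families
#: (ATG/Met, TGG/Trp, whose w is 1 by construction) and stop codons.
DEFAULT_EXCLUSIONS: frozenset[str] = frozenset({"ATG", "TGG"} | set(_STANDARD.stop_codons))

#: Sharp & Li pseudo-count replacing zero usage frequencies.
DEFAULT_PSEUDO = 0.5

_KAZUSA_ENTRY = re.compile(r"([ACGTUacgtu]{3})\s+([0-9]*\.?[0-9]+)(?:\s*\(\s*([0-9]+)\s*\))?")


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon usage frequencies (per-thousand or raw counts) for one species.

    Frequencies are only ever compared within synonymous families, so
    per-thousand values and raw counts behave identically.
    """

    species: str
    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.entries)
        if keys != set(ALL_CODONS):
            bad = sorted((keys - set(ALL_CODONS)) | (set(ALL_CODONS) - keys))
            raise TableError(f"table must cover exactly the 64 codons; problem: {bad[:8]}")
        if any(v < 0 for v in self.entries.values()):
            raise TableError("frequencies must be non-negative")


@dataclass(frozen=True)
class AdaptivenessTable:
    """Relative adaptiveness ``w`` per codon, max 1 within each family."""

    species: str
    w: Mapping[str, float] = field(default_factory=dict)

    def __getitem__(self, codon: str) -> float:
        return self.w[codon]


def read_codon_usage(source, species: str = "") -> CodonUsageTable:
    """Parse a codon usage table from Kazusa-style free text or a
    two-column (codon, frequency) TSV/CSV. ``source`` is a path or a str
    of the table text. RNA codons (U) are accepted and converted to DNA.
    """
    looks_like_path = isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and len(source) < 4096)
    if looks_like_path and Path(str(source)).is_file():
        text = Path(source).read_text()
        if not species:
            species = Path(source).stem
    else:
        text = str(source)
    entries: dict[str, float] = {}
    for m in _KAZUSA_ENTRY.finditer(text):
        codon = m.group(1).upper().replace("U", "T")
        if codon not in CODON_TO_AA:
            raise TableError(f"malformed codon key {m.group(1)!r}")
        if codon in entries:
            raise TableError(f"duplicate codon {codon}")
        entries[codon] = float(m.group(2))
    if set(entries) != set(ALL_CODONS):
        missing = sorted(set(ALL_CODONS) - set(entries))
        raise TableError(f"table incomplete; missing {len(missing)} codons, e.g. {missing[:6]}")
    return CodonUsageTable(species=species or "unknown", entries=entries)


def relative_adaptiveness(
    table: CodonUsageTable,
    pseudo: float = DEFAULT_PSEUDO,
) -> AdaptivenessTable:
    """Sharp & Li relative adaptiveness weights.

    Zero frequencies are replaced by ``pseudo`` before dividing each
    codon's frequency by the maximum within its synonymous family, so all
    ``w`` lie in (0, 1] and every family attains w = 1.
    """
    if pseudo <= 0:
        raise TableError("pseudo-count must be positive")
    freq = {c: (f if f > 0 else pseudo) for c, f in table.entries.items()}
    w: dict[str, float] = {}
    for _aa, codons in SYNONYMOUS_FAMILIES.items():
        fmax = max(freq[c] for c in codons)
        for c in codons:
            w[c] = freq[c] / fmax
    return AdaptivenessTable(species=table.species, w=w)


def _split_codons(cds: str) -> list[str]:
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise SequenceError(f"length {len(seq)} not divisible by 3")
    if re.search(r"[^ACGT]", seq):
        bad = sorted(set(re.findall(r"[^ACGT]", seq)))
        raise SequenceError(f"non-ACGT symbols in sequence: {bad}")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def cai(
    cds: str,
    weights: AdaptivenessTable,
    exclusions: frozenset[str] | set[str] = DEFAULT_EXCLUSIONS,
) -> float:
    """Codon adaptation index of a coding sequence.

    Geometric mean of the relative adaptiveness of all non-excluded
    codons, evaluated in the log domain so long sequences do not
    underflow.

    Raises
    ------
    SequenceError
        On length not divisible by 3, ambiguity codes, or when every
        codon is excluded (CAI undefined).
    """
    codons = [c for c in _split_codons(cds) if c not in exclusions]
    if not codons:
        raise SequenceError("all codons excluded: CAI undefined")
    log_sum = sum(math.log(weights[c]) for c in codons)
    return math.exp(log_sum / len(codons))


def translate(cds: str) -> str:
    """Translate a CDS (standard code); trailing stop is kept as '*'."""
    return str(Seq("".join(_split_codons(cds))).translate())


def codon_average(
    protein_or_cds: str,
    table: CodonUsageTable,
    mode: str = "most_frequent",
    seed: int = 0,
) -> str:
    """Back-translate a protein using a species codon-usage table.

    ``protein_or_cds`` may be an amino-acid sequence ('*' allowed as a
    trailing stop) or a DNA CDS, which is translated first (internal
    stops rejected). Mode ``most_frequent`` picks each residue's
    highest-frequency codon (ties broken alphabetically); mode
    ``usage_weighted`` samples each codon from the within-family usage
    frequencies with the given seed. The output always translates back to
    the input protein.
    """
    seq = protein_or_cds.upper()
    if re.fullmatch(r"[ACGTU]+", seq) and len(seq) % 3 == 0:
        protein = translate(seq)
        if "*" in protein[:-1]:
            raise SequenceError("CDS contains an internal stop codon")
    else:
        protein = seq
    aas = list(protein)
    unknown = sorted(set(aas) - set(SYNONYMOUS_FAMILIES))
    if unknown:
        raise SequenceError(f"residues without codons in the standard code: {unknown}")
    if mode not in ("most_frequent", "usage_weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for aa in aas:
        codons = SYNONYMOUS_FAMILIES[aa]
        freqs = np.array([table.entries[c] for c in codons], dtype=float)
        if freqs.sum() <= 0:
            raise TableError(f"amino acid {aa!r}: no positive-frequency codon")
        if mode == "most_frequent":
            # alphabetical tie-break: codons are sorted, argmax takes the first max
            out.append(codons[int(np.argmax(freqs))])
        else:
            out.append(codons[int(rng.choice(len(codons), p=freqs / freqs.sum()))])
    return "".join(out)


def cai_report(
    sequences: Mapping[str, str],
    tables: Mapping[str, CodonUsageTable],
    pseudo: float = DEFAULT_PSEUDO,
    exclusions: frozenset[str] | set[str] = DEFAULT_EXCLUSIONS,
):
    """Per-sequence CAI against each species table (long DataFrame)."""
    import pandas as pd

    weights = {sp: relative_adaptiveness(t, pseudo) for sp, t in tables.items()}
    rows = [{"sequence": name, "species": sp, "cai": cai(s, weights[sp], exclusions)}
            for name, s in sequences.items() for sp in tables]
    return pd.DataFrame(rows, columns=["sequence", "species", "cai"])
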