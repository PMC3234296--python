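"""Sequence-derived covariates for qPCR efficiency modelling.

Given an amplicon and its primer pair this module computes every covariate
used downstream: lengths and G+C fractions, homopolymer runs (N6-or-above
repeats), reverse-complement palindromes, primer melting temperatures,
3'-terminal features, and the triplet-based hybridization scores
(``primersSelfcom`` for a primer against itself, ``primerDimers`` for the
two primers against each other).

The triplet scores reduce each sequence to its overlapping 3-mers and count
3-mers shared between one sequence and the reverse complement of the other
(multiset intersection), a cheap proxy for the tendency of two strands to
hybridize.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .errors import ConfigurationError, InvalidSequenceError

__all__ = [
    "FEATURE_COLUMNS",
    "Amplicon",
    "FeatureRecord",
    "PrimerPair",
    "TerminalFeatures",
    "extract_features",
    "extract_triplets",
    "features_to_frame",
    "find_palindromes",
    "gc_content",
    "gc_imbalance",
    "homopolymer_runs",
    "melting_temperature",
    "normalize_sequence",
    "primer_dimers",
    "primer_selfcom",
    "reverse_complement",
    "terminal_features",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Column order of the feature-table CSV schema.
FEATURE_COLUMNS = [
    "lengthSequence", "gcSequence", "forLength", "revLength", "gcPrimers",
    "aRepeats", "tRepeats", "cRepeats", "gRepeats",
    "aCount", "tCount", "cCount", "gCount",
    "tmForward", "tmReverse", "primerDimers", "primersSelfcom",
    "trap3For", "trap3Rev", "trap3LastFor", "trap3LastRev",
    "sequencePalindromes", "primersLength", "gcImbalance",
    "machine", "template", "source", "operator", "species", "var",
    "efficiency",
]

#: Free-string metadata fields carried through to the table, never modelled.
METADATA_FIELDS = ["machine", "template", "source", "operator", "species", "var"]


def normalize_sequence(seq: str, name: str = "sequence", min_len: int = 1) -> str:
    """Uppercase *seq* and validate it against the strict ACGT alphabet.

    IUPAC ambiguity codes are rejected: the features computed here are only
    meaningful on fully specified sequences.
    """
    if not isinstance(seq, str):
        raise InvalidSequenceError(f"{name} must be a string, got {type(seq).__name__}")
    seq = seq.strip().upper()
    if len(seq) < min_len:
        raise InvalidSequenceError(
            f"{name} must have at least {min_len} nucleotide(s), got {len(seq)}"
        )
    for ch in seq:
        if ch not in BASES:
            raise InvalidSequenceError(
                f"{name} contains invalid character {ch!r}; only A/C/G/T are allowed"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Fraction of G or C bases, in [0, 1]."""
    seq = normalize_sequence(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def homopolymer_runs(seq: str, min_repeat: int = 6) -> dict:
    """Longest homopolymer run per base and the run >= *min_repeat* flag.

    Returns a dict with keys ``aCount`` .. ``gCount`` (longest run of that
    base, 0 if absent) and ``aRepeats`` .. ``gRepeats`` (run length at least
    *min_repeat*, the usual "N6 or above" convention).
    """
    seq = normalize_sequence(seq)
    longest = dict.fromkeys(BASES, 0)
    run_base, run_len = "", 0
    for ch in seq:
        run_len = run_len + 1 if ch == run_base else 1
        run_base = ch
        if run_len > longest[ch]:
            longest[ch] = run_len
    out = {}
    for b in BASES:
        out[f"{b.lower()}Count"] = longest[b]
        out[f"{b.lower()}Repeats"] = longest[b] >= min_repeat
    return out


def extract_triplets(seq: str) -> list[str]:
    """Overlapping 3-mers of *seq* in order (sliding window, step 1)."""
    seq = normalize_sequence(seq, min_len=3)
    return [seq[i : i + 3] for i in range(len(seq) - 2)]


def _triplet_overlap(a: str, b: str) -> int:
    """Multiset-intersection size of the overlapping 3-mers of two strings."""
    ca, cb = Counter(extract_triplets(a)), Counter(extract_triplets(b))
    return sum(min(n, cb[t]) for t, n in ca.items())


def primer_selfcom(primer: str, normalized: bool = False) -> float:
    """Self-complementarity score: 3-mers shared between a primer and its
    reverse complement (multiset intersection).

    With ``normalized=True`` the raw count is divided by the number of
    triplets in the primer, giving a score in [0, 1].
    """
    primer = normalize_sequence(primer, "primer", min_len=3)
    count = _triplet_overlap(primer, reverse_complement(primer))
    return count / (len(primer) - 2) if normalized else count


def primer_dimers(forward: str, reverse: str, normalized: bool = False) -> float:
    """Cross-hybridization score: 3-mers shared between the forward primer
    and the reverse complement of the reverse primer.

    With ``normalized=True`` the count is divided by the maximum attainable
    overlap (the smaller triplet count of the two primers).
    """
    forward = normalize_sequence(forward, "forward primer", min_len=3)
    reverse = normalize_sequence(reverse, "reverse primer", min_len=3)
    count = _triplet_overlap(forward, reverse_complement(reverse))
    if normalized:
        return count / min(len(forward) - 2, len(reverse) - 2)
    return count


def gc_imbalance(forward: str, reverse: str) -> float:
    """Absolute difference in G+C fraction between the two primers."""
    return abs(gc_content(forward) - gc_content(reverse))


def melting_temperature(
    primer: str,
    method: str = "nearest_neighbor",
    na_mm: float = 50.0,
    oligo_nm: float = 240.0,
) -> float:
    """Primer melting temperature in degrees Celsius.

    ``nearest_neighbor`` uses the unified duplex thermodynamic parameters
    (Biopython's ``Tm_NN``) at *na_mm* mM monovalent salt and *oligo_nm* nM
    oligonucleotide; the defaults are 50 mM Na+ and the 240 nM per-primer
    reaction concentration the training data were produced at.
    ``wallace`` is the 2(A+T)+4(G+C) rule of thumb.
    """
    if method == "wallace":
        primer = normalize_sequence(primer, "primer")
        at = primer.count("A") + primer.count("T")
        gc = primer.count("G") + primer.count("C")
        return 2.0 * at + 4.0 * gc
    if method == "nearest_neighbor":
        primer = normalize_sequence(primer, "primer", min_len=2)
        return float(
            MeltingTemp.Tm_NN(primer, Na=na_mm, dnac1=oligo_nm, dnac2=0.0)
        )
    raise ConfigurationError(
        f"unknown Tm method {method!r}; use 'nearest_neighbor' or 'wallace'"
    )


def find_palindromes(seq: str, min_len: int = 6) -> int:
    """Count reverse-complement palindromes of length >= *min_len*.

    A substring is counted when it equals its own reverse complement (such
    substrings necessarily have even length, e.g. the EcoRI site GAATTC).
    Each start position contributes at most once, at its maximal palindromic
    extent, so nested shorter palindromes at the same start are not
    recounted.  The default minimum length 6 mirrors the N6 repeat
    convention used for homopolymers.
    """
    if min_len % 2 != 0 or min_len < 4:
        raise ConfigurationError(f"min_len must be an even integer >= 4, got {min_len}")
    seq = normalize_sequence(seq)
    n = len(seq)
    half = min_len // 2
    comp = seq.translate(_COMPLEMENT)
    # Expand around each inter-base center: seq[j-r:j] reverse-complement
    # pairs with seq[j:j+r] iff seq[j-1-k] == complement(seq[j+k]) for k < r.
    starts: set[int] = set()
    for j in range(1, n):
        r = 0
        while j - r - 1 >= 0 and j + r < n and seq[j - r - 1] == comp[j + r]:
            r += 1
        if r >= half:
            # palindromes of radius half..r start at j-r .. j-half;
            # the maximal extent for start i is radius j-i.
            starts.update(range(j - r, j - half + 1))
    return len(starts)


@dataclass(frozen=True)
class TerminalFeatures:
    """3'-terminal dinucleotide, last base, and purine/pyrimidine class."""

    dinucleotide: str
    last: str
    purine_class: str  # "U" purine (A/G), "Y" pyrimidine (C/T)


def terminal_features(primer: str) -> TerminalFeatures:
    """3'-end features of a primer (its last two and last one nucleotides)."""
    primer = normalize_sequence(primer, "primer", min_len=2)
    last = primer[-1]
    return TerminalFeatures(primer[-2:], last, "U" if last in "AG" else "Y")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse oligo pair, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self):
        object.__setattr__(self, "forward",
                           normalize_sequence(self.forward, "forward primer", min_len=3))
        object.__setattr__(self, "reverse",
                           normalize_sequence(self.reverse, "reverse primer", min_len=3))

    @property
    def for_length(self) -> int:
        return len(self.forward)

    @property
    def rev_length(self) -> int:
        return len(self.reverse)


@dataclass(frozen=True)
class Amplicon:
    """The template segment amplified between the two primers."""

    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence",
                           normalize_sequence(self.sequence, "amplicon"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureRecord:
    """One row of the feature-table schema: all covariates plus metadata.

    ``efficiency`` is the measured amplification efficiency in [1, 2] when
    known, or None for prediction-only records.
    """

    lengthSequence: int
    gcSequence: float
    forLength: int
    revLength: int
    gcPrimers: float
    aRepeats: bool
    tRepeats: bool
    cRepeats: bool
    gRepeats: bool
    aCount: int
    tCount: int
    cCount: int
    gCount: int
    tmForward: float
    tmReverse: float
    primerDimers: float
    primersSelfcom: float
    trap3For: str
    trap3Rev: str
    trap3LastFor: str
    trap3LastRev: str
    sequencePalindromes: int
    primersLength: float
    gcImbalance: float
    machine: str = ""
    template: str = ""
    source: str = ""
    operator: str = ""
    species: str = ""
    var: str = ""
    efficiency: float | None = None

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in FEATURE_COLUMNS}


def extract_features(
    amplicon: Amplicon | str,
    primers: PrimerPair,
    metadata: dict | None = None,
    efficiency: float | None = None,
    tm_method: str = "nearest_neighbor",
) -> FeatureRecord:
    """Compute the full covariate record for one amplicon/primer-pair combination.

    ``primersLength`` is the arithmetic mean of the two primer lengths and
    ``gcPrimers`` the G+C fraction of the concatenated primers, so both stay
    on per-primer units.  Whether the primers actually anneal to the
    amplicon is deliberately not checked.
    """
    if isinstance(amplicon, str):
        amplicon = Amplicon(amplicon)
    if len(amplicon) < primers.for_length + primers.rev_length:
        raise InvalidSequenceError(
            f"amplicon ({len(amplicon)} nt) is shorter than the combined "
            f"primer length ({primers.for_length + primers.rev_length} nt)"
        )
    meta = {f: "" for f in METADATA_FIELDS}
    if metadata:
        unknown = set(metadata) - set(METADATA_FIELDS)
        if unknown:
            raise ConfigurationError(f"unknown metadata fields: {sorted(unknown)}")
        meta.update({k: str(v) for k, v in metadata.items()})
    seq = amplicon.sequence
    runs = homopolymer_runs(seq)
    t_for = terminal_features(primers.forward)
    t_rev = terminal_features(primers.reverse)
    return FeatureRecord(
        lengthSequence=len(seq),
        gcSequence=gc_content(seq),
        forLength=primers.for_length,
        revLength=primers.rev_length,
        gcPrimers=gc_content(primers.forward + primers.reverse),
        tmForward=melting_temperature(primers.forward, tm_method),
        tmReverse=melting_temperature(primers.reverse, tm_method),
        primerDimers=primer_dimers(primers.forward, primers.reverse),
        primersSelfcom=primer_selfcom(primers.forward)
        + primer_selfcom(primers.reverse),
        trap3For=t_for.dinucleotide,
        trap3Rev=t_rev.dinucleotide,
        trap3LastFor=t_for.last,
        trap3LastRev=t_rev.last,
        sequencePalindromes=find_palindromes(seq),
        primersLength=statistics.mean((primers.for_length, primers.rev_length)),
        gcImbalance=gc_imbalance(primers.forward, primers.reverse),
        efficiency=efficiency,
        **runs,
        **meta,
    )


def features_to_frame(records) -> pd.DataFrame:
    """Stack FeatureRecords (or an id->record mapping) into a DataFrame."""
    if isinstance(records, dict):
        ids = list(records)
        rows = [records[i].to_dict() for i in ids]
        return pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    return pd.DataFrame([r.to_dict() for r in records])
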