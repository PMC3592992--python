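"""Reading and filtering samtools pileup text.

One pileup line describes one genomic position: chromosome, 1-based position,
reference base, coverage, a read-base string in pileup syntax, and an ASCII
phred quality string.  An optional seventh column may carry the ancestral
allele.  All coordinates here (pileup and GTF) are 1-based inclusive.
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .spectrum import read_spectrum_file, write_spectrum_file  # noqa: F401  (module surface)

__all__ = [
    "AncestralMode",
    "PileupSite",
    "PileupParseError",
    "parse_pileup_line",
    "read_pileup",
    "filter_pileup_by_gtf",
    "subsample_positions",
    "read_spectrum_file",
    "write_spectrum_file",
]

NUCLEOTIDES = "ACGT"
UNKNOWN = "?"  #: placeholder ancestral base when the mode is 'unknown'


class AncestralMode(enum.Enum):
    """How the ancestral allele of each site is determined.

    ``unknown``   -- no ancestral information; the analysis is folded.
    ``reference`` -- the pileup reference base is taken as ancestral.
    ``provided``  -- a seventh pileup column carries the ancestral base.
    """

    UNKNOWN = "unknown"
    REFERENCE = "reference"
    PROVIDED = "provided"


class PileupParseError(ValueError):
    pass


@dataclass
class PileupSite:
    """One parsed pileup position.

    ``bases`` holds the cleaned base calls (A/C/G/T only, uppercased, with
    pileup markup and non-allelic symbols removed) and ``error_probs`` the
    matching per-base sequencing-error probabilities ``10**(-Q/10)``.
    """

    chrom: str
    pos: int
    ref_base: str
    ancestral: str
    bases: str
    error_probs: np.ndarray

    @property
    def coverage(self) -> int:
        return len(self.bases)


def _clean_base_string(raw: str, ref_base: str, where: str) -> tuple[str, list[int], int]:
    """Walk the pileup read-base grammar.

    Returns the retained base letters, the index of each retained call into
    the quality string, and the total number of quality-consuming symbols
    (retained calls plus dropped 'N'/'*'/'>'/'<' symbols).
    """
    bases: list[str] = []
    qual_idx: list[int] = []
    i = 0
    q = 0  # index into the quality string
    n_raw = len(raw)
    while i < n_raw:
        c = raw[i]
        if c == "^":
            if i + 1 >= n_raw:
                raise PileupParseError(f"{where}: dangling '^' in read-base string")
            i += 2  # skip the mapping-quality character, not used
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n_raw and raw[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"{where}: indel marker without length")
            length = int(raw[i + 1 : j])
            i = j + length
            continue
        if c in ".,":
            bases.append(ref_base)
            qual_idx.append(q)
            q += 1
        elif c in "ACGTacgt":
            bases.append(c.upper())
            qual_idx.append(q)
            q += 1
        elif c in "Nn*><":
            q += 1  # consumes a quality character but carries no allele
        else:
            raise PileupParseError(f"{where}: unrecognized pileup symbol {c!r}")
        i += 1
    return "".join(bases), qual_idx, q


def parse_pileup_line(
    line: str,
    mode: AncestralMode = AncestralMode.UNKNOWN,
    quality_offset: int = 33,
    line_number: int | None = None,
    min_quality: int = 0,
) -> PileupSite:
    """Parse one pileup line into a :class:`PileupSite`.

    Parameters
    ----------
    mode : AncestralMode
        Sets the ``ancestral`` field: the reference base, the seventh column,
        or the ``?`` placeholder for folded analyses.
    quality_offset : int
        ASCII offset of the phred encoding, 33 (Sanger/Illumina 1.8+) or 64.
    min_quality : int
        Optional base-quality floor; calls below it are dropped with their
        quality (default 0 = keep everything, letting the likelihood weight
        low-quality calls continuously).
    """
    where = f"line {line_number}" if line_number is not None else "pileup line"
    fields = line.split()
    need = 7 if mode is AncestralMode.PROVIDED else 6
    if len(fields) < need:
        raise PileupParseError(f"{where}: expected >= {need} fields, found {len(fields)}")
    chrom, pos_s, ref_base, cov_s, base_str, qual_str = fields[:6]
    try:
        pos = int(pos_s)
        raw_cov = int(cov_s)
    except ValueError as exc:
        raise PileupParseError(f"{where}: non-integer position or coverage") from exc
    ref_base = ref_base.upper()

    if raw_cov == 0 and base_str == "*":
        # samtools writes '* *' placeholders at uncovered positions
        bases, qual_idx, n_qual_symbols = "", [], 0
        qual_str = "" if qual_str == "*" else qual_str
    else:
        bases, qual_idx, n_qual_symbols = _clean_base_string(base_str, ref_base, where)
    if len(qual_str) != n_qual_symbols:
        raise PileupParseError(
            f"{where}: {n_qual_symbols} quality-consuming calls but "
            f"{len(qual_str)} quality characters"
        )
    quals = np.array([ord(qual_str[i]) - quality_offset for i in qual_idx], dtype=float)
    if np.any(quals < 0):
        raise PileupParseError(
            f"{where}: quality character below offset {quality_offset}; "
            "is the quality encoding offset (--quality-offset) correct?"
        )
    if min_quality > 0 and quals.size:
        keep = quals >= min_quality
        bases = "".join(b for b, k in zip(bases, keep) if k)
        quals = quals[keep]
    error_probs = 10.0 ** (-quals / 10.0)

    if mode is AncestralMode.REFERENCE:
        ancestral = ref_base
    elif mode is AncestralMode.PROVIDED:
        ancestral = fields[6].upper()
        if ancestral not in NUCLEOTIDES:
            raise PileupParseError(f"{where}: invalid ancestral allele {fields[6]!r}")
    else:
        ancestral = UNKNOWN
    return PileupSite(chrom, pos, ref_base, ancestral, bases, error_probs)


def read_pileup(
    path,
    mode: AncestralMode = AncestralMode.UNKNOWN,
    quality_offset: int = 33,
    min_quality: int = 0,
) -> Iterator[PileupSite]:
    """Stream :class:`PileupSite` records from a pileup file."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            yield parse_pileup_line(
                line, mode, quality_offset, line_number=i, min_quality=min_quality
            )


def _merged_feature_intervals(gtf_path, feature: str) -> dict[str, tuple[list[int], list[int]]]:
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    present = sorted(db.featuretypes())
    if feature not in present:
        raise ValueError(
            f"feature type {feature!r} not in annotation; present types: {', '.join(present)}"
        )
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type(feature):
        by_chrom.setdefault(feat.seqid, []).append((feat.start, feat.end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivs:
            if starts and s <= ends[-1] + 1:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (starts, ends)
    return merged


def filter_pileup_by_gtf(
    sites: Iterable[PileupSite], gtf_path, feature: str
) -> Iterator[PileupSite]:
    """Keep only sites inside >= 1 interval of the requested GTF feature type.

    Intervals are merged per chromosome before testing; GTF coordinates are
    1-based inclusive.  Output order equals input order.
    """
    merged = _merged_feature_intervals(gtf_path, feature)
    for site in sites:
        chrom_ivs = merged.get(site.chrom)
        if chrom_ivs is None:
            continue
        starts, ends = chrom_ivs
        i = bisect_right(starts, site.pos) - 1
        if i >= 0 and site.pos <= ends[i]:
            yield site


def subsample_positions(
    sites: Iterable[PileupSite], ratio: int, seed: int
) -> Iterator[PileupSite]:
    """Keep each site independently with probability ``1/ratio`` (seeded).

    ``ratio=1`` passes everything through untouched; the same seed and input
    always select the same subset.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    if ratio == 1:
        yield from sites
        return
    rng = np.random.default_rng(seed)
    p = 1.0 / ratio
    for site in sites:
        if rng.random() < p:
            yield site
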