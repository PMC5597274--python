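"""Physicochemical amino-acid indices and the AAindex1 flat-file format.

An *amino-acid index* assigns one real number to each of the 20 standard
residues (e.g. hydropathy, isoelectric point, van der Waals volume).  The
public AAindex1 database distributes such indices as flat-text records; this
module reads and writes that format and ships the 13-index table used for
position-resolved tripeptide encoding (see :mod:`pepfocus.library_design`).

The bundled table is frozen into the package so that no network or external
database is ever consulted at run time.  The accession chosen for each of the
13 descriptions is recorded in ``docs/provenance.md`` of the source
distribution.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue order of the value block in an AAindex1 record: first line
#: A R N D C Q E G H I, second line L K M F P S T W Y V.
AAINDEX1_COLUMN_ORDER: str = "ARNDCQEGHI" + "LKMFPSTWYV"


class AAindexParseError(ValueError):
    """Raised when an AAindex1 stream cannot be parsed."""


@dataclass(frozen=True)
class AminoAcidIndex:
    """One amino-acid index: an accession, a description and 20 values."""

    accession: str
    description: str
    values: dict[str, float]
    reference: str = ""
    authors: str = ""
    journal: str = ""

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - keys)
            extra = sorted(keys - set(AMINO_ACIDS))
            raise ValueError(
                f"index {self.accession!r} must map exactly the 20 standard "
                f"residues (missing {missing}, unexpected {extra})"
            )
        for aa, v in self.values.items():
            if not _finite(v):
                raise ValueError(
                    f"index {self.accession!r} has non-finite value for {aa!r}: {v!r}"
                )

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


@dataclass(frozen=True)
class IndexTable:
    """An ordered collection of amino-acid indices.

    The bundled table holds the 13 indices used for tripeptide encoding, in
    their canonical numbering (1 = isoelectric point ... 13 = amino acid
    distribution).
    """

    indices: tuple[AminoAcidIndex, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        accs = [ix.accession for ix in self.indices]
        if len(set(accs)) != len(accs):
            raise ValueError(f"duplicate accessions in table: {accs}")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __getitem__(self, i: int) -> AminoAcidIndex:
        return self.indices[i]


def _finite(x: float) -> bool:
    return x == x and x not in (float("inf"), float("-inf"))


def parse_aaindex1(stream: TextIO | str) -> list[AminoAcidIndex]:
    """Parse AAindex1 flat-file records from ``stream``.

    Records are delimited by ``//``.  Each record needs an ``H`` (accession)
    line and an ``I`` line followed by two lines of ten numbers in the
    canonical AAindex1 column order (A/L, R/K, N/M, D/F, C/P, Q/S, E/T, G/W,
    H/Y, I/V).  Records whose value block contains ``NA`` are skipped with a
    warning.

    Raises
    ------
    AAindexParseError
        If a record lacks its ``H`` or ``I`` line (the error names the byte
        offset of the record) or contains a non-numeric value (the error
        names the accession).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    indices: list[AminoAcidIndex] = []
    offset = 0  # byte offset of the current record's first character
    record_lines: list[str] = []
    record_start = 0
    saw_record_content = False

    def flush(start: int, lines: list[str]) -> None:
        idx = _parse_record(start, lines)
        if idx is not None:
            indices.append(idx)

    for line in text.splitlines(keepends=True):
        stripped = line.rstrip("\n")
        if stripped.strip() == "//":
            flush(record_start, record_lines)
            record_lines = []
            record_start = offset + len(line.encode())
            saw_record_content = False
        else:
            if not record_lines and stripped.strip():
                record_start = offset
            if stripped.strip():
                saw_record_content = True
            record_lines.append(stripped)
        offset += len(line.encode())
    if saw_record_content and any(l.strip() for l in record_lines):
        raise AAindexParseError(
            f"record at byte offset {record_start} is not terminated by '//'"
        )
    if not indices:
        raise AAindexParseError("stream contains no AAindex1 records")
    return indices


def _parse_record(offset: int, lines: list[str]) -> AminoAcidIndex | None:
    lines = [l for l in lines if l.strip()]
    if not lines:
        return None
    fields: dict[str, str] = {}
    value_tokens: list[str] = []
    in_values = False
    for line in lines:
        tag, _, rest = line.partition(" ")
        if tag == "I":
            in_values = True  # the I line itself carries the column mnemonics
            continue
        if tag in ("H", "D", "R", "A", "T", "J", "C"):
            in_values = False
            fields[tag] = (fields.get(tag, "") + " " + rest.strip()).strip()
            continue
        if in_values:
            value_tokens.extend(line.split())
    if "H" not in fields:
        raise AAindexParseError(
            f"record at byte offset {offset} has no H (accession) line"
        )
    accession = fields["H"].split()[0]
    if not value_tokens:
        raise AAindexParseError(
            f"record at byte offset {offset} ({accession}) has no I (value) line"
        )
    if "NA" in value_tokens:
        logger.warning("skipping AAindex record %s: contains NA values", accession)
        return None
    if len(value_tokens) != 20:
        raise AAindexParseError(
            f"record {accession} has {len(value_tokens)} values, expected 20"
        )
    values: dict[str, float] = {}
    for aa, tok in zip(AAINDEX1_COLUMN_ORDER, value_tokens):
        try:
            values[aa] = float(tok)
        except ValueError as exc:
            raise AAindexParseError(
                f"record {accession}: non-numeric value {tok!r} for residue {aa}"
            ) from exc
    return AminoAcidIndex(
        accession=accession,
        description=fields.get("D", ""),
        values=values,
        reference=fields.get("R", ""),
        authors=fields.get("A", ""),
        journal=fields.get("J", ""),
    )


def write_aaindex1(indices: Iterable[AminoAcidIndex], stream: TextIO) -> None:
    """Write indices in AAindex1 flat-file format (round-trips exactly)."""
    for ix in indices:
        stream.write(f"H {ix.accession}\n")
        if ix.description:
            stream.write(f"D {ix.description}\n")
        if ix.reference:
            stream.write(f"R {ix.reference}\n")
        if ix.authors:
            stream.write(f"A {ix.authors}\n")
        if ix.journal:
            stream.write(f"J {ix.journal}\n")
        stream.write(
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
        )
        vals = [ix.values[aa] for aa in AAINDEX1_COLUMN_ORDER]
        # .17g preserves every double exactly on re-parse
        stream.write("  " + " ".join(f"{v:>7.17g}" for v in vals[:10]) + "\n")
        stream.write("  " + " ".join(f"{v:>7.17g}" for v in vals[10:]) + "\n")
        stream.write("//\n")


def table_to_tsv(table: IndexTable, stream: TextIO) -> None:
    """Export an index table as TSV: index_number, accession, description, A..Y."""
    stream.write(
        "index_number\taccession\tdescription\t" + "\t".join(AMINO_ACIDS) + "\n"
    )
    for n, ix in enumerate(table, start=1):
        vals = "\t".join(f"{ix.values[aa]:.17g}" for aa in AMINO_ACIDS)
        stream.write(f"{n}\t{ix.accession}\t{ix.description}\t{vals}\n")


def bundled_table() -> IndexTable:
    """The packaged 13-index table used for tripeptide encoding.

    Index numbering follows the canonical order: 1 isoelectric point,
    2 normalized van der Waals volume, 3 alpha-helix indices for
    beta-proteins, 4 beta-strand indices for beta-proteins, 5 side-chain
    contribution to protein stability, 6 stability scale from the
    knowledge-based atom-atom potential, 7 hydropathy index, 8 normalized
    frequency of turn, 9 free energy in beta-strand region, 10 free energy
    in alpha-helical region, 11 polarity, 12 side chain interaction
    parameter, 13 amino acid distribution.
    """
    indices = parse_aaindex1(_BUNDLED_AAINDEX1)
    assert len(indices) == 13
    return IndexTable(tuple(indices))


# Verbatim AAindex1 records for the 13 bundled indices (accessions resolved
# from the descriptions above; see docs/provenance.md).
_BUNDLED_AAINDEX1 = """\
H ZIMJ680104
D Isoelectric point (Zimmerman et al., 1968)
R LIT:2004109b PMID:5700434
A Zimmerman, J.M., Eliezer, N. and Simha, R.
J J. Theor. Biol. 21, 170-201 (1968)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
        6   10.76    5.41    2.77    5.05    5.65    3.22    5.97    7.59    6.02
     5.98    9.74    5.74    5.48     6.3    5.68    5.66    5.89    5.66    5.96
//
H FAUJ880103
D Normalized van der Waals volume (Fauchere et al., 1988)
R LIT:1414114 PMID:3209351
A Fauchere, J.L., Charton, M., Kier, L.B., Verloop, A. and Pliska, V.
J Int. J. Peptide Protein Res. 32, 269-278 (1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
        1    6.13    2.95    2.78    2.43    3.95    3.78       0    4.66       4
        4    4.77    4.43    5.89    2.72     1.6     2.6    8.08    6.47       3
//
H GEIM800103
D Alpha-helix indices for beta-proteins (Geisow-Roberts, 1980)
R LIT:0701087b
A Geisow, M.J. and Roberts, R.D.B.
J Int. J. Biol. Macromol. 2, 387-389 (1980)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.55     0.2     1.2    1.55    1.44    1.13    1.67    0.59    1.21    1.27
     1.25     1.2    1.37     0.4    0.21    1.01    0.55    1.86    1.08    0.64
//
H GEIM800106
D Beta-strand indices for beta-proteins (Geisow-Roberts, 1980)
R LIT:0701087b
A Geisow, M.J. and Roberts, R.D.B.
J Int. J. Biol. Macromol. 2, 387-389 (1980)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.86    1.15     0.6    0.66    0.91    1.11    0.37    0.86    1.07    1.17
     1.28    1.01    1.15    1.34    0.61    0.91    1.14    1.13    1.37    1.31
//
H TAKK010101
D Side-chain contribution to protein stability (kJ/mol) (Takano-Yutani, 2001)
R PMID:11579219
A Takano, K., Yutani, K.
J Protein Eng. 14, 525-528 (2001)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      9.8     7.3     3.6     4.9       3     2.4     4.4       0    11.9    17.2
       17    10.5    11.9      23      15     2.6     6.9    24.2    17.2    15.3
//
H ZHOH040101
D The stability scale from the knowledge-based atom-atom potential (Zhou-Zhou, 2004)
R PMID:14696193
A Zhou, H. and Zhou, Y.
J Proteins 54, 315-322 (2004)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     2.18    2.71    1.85    1.75    3.89    2.16    1.89    1.17    2.51     4.5
     4.71    2.12    3.63    5.88    2.09    1.66    2.18    6.46    5.01    3.77
//
H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
R LIT:0807099 PMID:7108955
A Kyte, J. and Doolittle, R.F.
J J. Mol. Biol. 157, 105-132 (1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
      3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7    -0.9    -1.3     4.2
//
H CRAJ730103
D Normalized frequency of turn (Crawford et al., 1973)
R PMID:4510294
A Crawford, J.L., Lipscomb, W.N. and Schellman, C.G.
J Proc. Natl. Acad. Sci. USA 70, 538-542 (1973)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      0.6    0.79    1.42    1.24    1.29    0.92    0.64    1.38    0.95    0.67
      0.7     1.1    0.67    1.05    1.47    1.26    1.05    1.23    1.35    0.48
//
H MUNV940104
D Free energy in beta-strand region (Munoz-Serrano, 1994)
R LIT:2105109 PMID:7731949
A Munoz, V. and Serrano, L.
J Proteins 20, 301-311 (1994)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.978   0.784   0.915   1.038   0.573   0.863   0.962   1.405   0.724   0.502
    0.766   0.841   0.729   0.585   2.613   0.784   0.569   0.671    0.56   0.444
//
H MUNV940102
D Free energy in alpha-helical region (Munoz-Serrano, 1994)
R LIT:2105109 PMID:7731949
A Munoz, V. and Serrano, L.
J Proteins 20, 301-311 (1994)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.619   0.753   1.089   0.932   1.107    0.77   0.675   1.361   1.034   0.876
     0.74   0.784   0.736   0.968    1.78   0.969   1.053    0.91   1.009   0.939
//
H GRAR740102
D Polarity (Grantham, 1974)
R LIT:2004143b PMID:4843792
A Grantham, R.
J Science 185, 862-864 (1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      8.1    10.5    11.6      13     5.5    10.5    12.3       9    10.4     5.2
      4.9    11.3     5.7     5.2       8     9.2     8.6     5.4     6.2     5.9
//
H KRIW790101
D Side chain interaction parameter (Krigbaum-Komoriya, 1979)
R LIT:0502056 PMID:760806
A Krigbaum, W.R. and Komoriya, A.
J Biochim. Biophys. Acta 576, 204-228 (1979)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     4.32    6.55    6.24    6.04    1.73    6.13    6.17    6.09    5.66    2.31
     3.93    7.92    2.44    2.59    7.19    5.37    5.16    2.78    3.58    3.31
//
H JUKT750101
D Amino acid distribution (Jukes et al., 1975)
R PMID:237322
A Jukes, T.H., Holmquist, R. and Moise, H.
J Science 189, 50-51 (1975)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      5.3     2.6       3     3.6     1.3     2.4     3.3     4.8     1.4     3.1
      4.7     4.1     1.1     2.3     2.5     4.5     3.7     0.8     2.3     4.2
//
"""
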