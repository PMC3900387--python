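"""Data model and I/O for ortholog alignments, phosphosites and kinase PWMs.

The central container is :class:`OrthologAlignment`: one pairwise protein
alignment carrying, per alignment column and per species, the amino acid,
the (observed) phosphorylation status and the structural disorder state.
The on-disk representation is a tab-delimited site table with one row per
alignment column and one character per cell:

    pair_id  <a>.aa  <a>.p  <a>.diso  <b>.aa  <b>.p  <b>.diso

where ``p`` is ``1`` (phosphorylated), ``0`` (not reported phosphorylated)
or ``-`` (gap), and ``diso`` is ``*`` (disordered), ``.`` (ordered) or
``-`` (gap). Rows belonging to one pair are contiguous and in column order;
``#``-prefixed lines are comments. Coordinates are 1-based throughout, for
both alignment columns and ungapped residue positions.

Kinase substrate preferences are 10-position amino-acid probability
matrices (phosphoacceptor at position 6), stored as blocks of the form::

    #KINASE=<name>
    A   C   D   ... Y      (20 columns, alphabetical)
    <10 probability rows>
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from Bio import SeqIO

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA20)}
PHOSPHO_RESIDUES = "STY"
GAP = "-"
PAD = "X"  # neutral symbol used to pad windows that run off a terminus
DISORDERED = "*"
ORDERED = "."

_P_SYMBOLS = "01-"
_DISO_SYMBOLS = "*.-"


class ParseError(ValueError):
    """Raised when a site table or PWM file violates the format contract."""


class MappingError(ValueError):
    """Raised when a phosphosite cannot be placed onto an alignment."""


def residue_class(residue: str) -> str | None:
    """Residue class used for compensation analyses: ``'ST'``, ``'Y'`` or None.

    Serine and threonine share hydroxyl chemistry and kinase families and
    form one class; tyrosine is its own class; anything else (including
    gaps) has no class.
    """
    if residue in "ST":
        return "ST"
    if residue == "Y":
        return "Y"
    return None


@dataclass
class OrthologAlignment:
    """A pairwise ortholog alignment with phospho and disorder tracks.

    All six tracks are strings of identical length. ``phospho`` uses
    ``'0'/'1'/'-'`` and ``diso`` uses ``'*'/'.'/'-'``; the gap symbol in the
    auxiliary tracks appears exactly where the amino-acid track has ``'-'``.
    """

    pair_id: str
    species_a_id: str
    species_b_id: str
    aa_a: str
    aa_b: str
    phospho_a: str
    phospho_b: str
    diso_a: str
    diso_b: str

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        n = len(self.aa_a)
        tracks = {
            "aa_a": self.aa_a, "aa_b": self.aa_b,
            "phospho_a": self.phospho_a, "phospho_b": self.phospho_b,
            "diso_a": self.diso_a, "diso_b": self.diso_b,
        }
        if n < 1:
            raise ValueError(f"{self.pair_id}: alignment must have length >= 1")
        for name, t in tracks.items():
            if len(t) != n:
                raise ValueError(
                    f"{self.pair_id}: track {name} has length {len(t)} != {n}")
        for sp, aa, p, d in (
            ("a", self.aa_a, self.phospho_a, self.diso_a),
            ("b", self.aa_b, self.phospho_b, self.diso_b),
        ):
            if set(aa) <= {GAP}:
                raise ValueError(f"{self.pair_id}: sequence {sp} is all gaps")
            for i, (r, pi, di) in enumerate(zip(aa, p, d), start=1):
                if r != GAP and r not in AA_INDEX:
                    raise ValueError(
                        f"{self.pair_id}: unknown residue {r!r} at column {i} ({sp})")
                if pi not in _P_SYMBOLS:
                    raise ValueError(
                        f"{self.pair_id}: bad phospho symbol {pi!r} at column {i} ({sp})")
                if di not in _DISO_SYMBOLS:
                    raise ValueError(
                        f"{self.pair_id}: bad disorder symbol {di!r} at column {i} ({sp})")
                if (r == GAP) != (pi == GAP) or (r == GAP) != (di == GAP):
                    raise ValueError(
                        f"{self.pair_id}: gap inconsistency at column {i} ({sp})")
                if pi == "1" and r not in PHOSPHO_RESIDUES:
                    raise ValueError(
                        f"{self.pair_id}: phospho flag on non-S/T/Y residue "
                        f"{r!r} at column {i} ({sp})")

    # -- basic accessors ------------------------------------------------

    def __len__(self) -> int:
        return len(self.aa_a)

    def _species_key(self, species: str) -> str:
        if species in (self.species_a_id, "a"):
            return "a"
        if species in (self.species_b_id, "b"):
            return "b"
        raise KeyError(f"unknown species {species!r} for pair {self.pair_id}")

    def aa(self, species: str) -> str:
        return self.aa_a if self._species_key(species) == "a" else self.aa_b

    def phospho(self, species: str) -> str:
        return self.phospho_a if self._species_key(species) == "a" else self.phospho_b

    def diso(self, species: str) -> str:
        return self.diso_a if self._species_key(species) == "a" else self.diso_b

    def ungapped_sequence(self, species: str) -> str:
        return self.aa(species).replace(GAP, "")

    # -- coordinate conversion ------------------------------------------

    def column_of(self, species: str, position: int) -> int:
        """Alignment column (1-based) of the ``position``-th residue."""
        aa = self.aa(species)
        n_res = len(aa) - aa.count(GAP)
        if not 1 <= position <= n_res:
            raise MappingError(
                f"{self.pair_id}: position {position} outside 1..{n_res} "
                f"({species})")
        seen = 0
        for col, r in enumerate(aa, start=1):
            if r != GAP:
                seen += 1
                if seen == position:
                    return col
        raise AssertionError("unreachable")

    def position_of(self, species: str, column: int) -> int:
        """Ungapped residue position (1-based) at alignment column."""
        aa = self.aa(species)
        if not 1 <= column <= len(aa):
            raise MappingError(f"{self.pair_id}: column {column} out of range")
        if aa[column - 1] == GAP:
            raise MappingError(
                f"{self.pair_id}: column {column} is a gap in {species}")
        return column - aa.count(GAP, 0, column)

    def copy(self) -> "OrthologAlignment":
        return replace(self)


@dataclass(frozen=True)
class PhosphoSite:
    """One reported phosphorylation event on an ungapped protein sequence."""

    protein_id: str
    species: str
    position: int  # 1-based ungapped residue index
    residue: str
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"{self.protein_id}:{self.position} residue {self.residue!r} "
                "is not phosphorylatable")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class SiteColumn:
    """One alignment column with residues, phospho flags and category."""

    column: int
    res_a: str
    res_b: str
    phos_a: bool | None  # None at gap
    phos_b: bool | None
    diso_a: str
    diso_b: str
    category: str
    residue_class_a: str | None = None
    residue_class_b: str | None = None


@dataclass
class KinasePWM:
    """A kinase substrate motif: 10 positions x 20 amino-acid probabilities.

    Position 6 (1-based) is the phosphoacceptor. Rows are probability
    vectors over :data:`AA20` in alphabetical order.
    """

    kinase: str
    matrix: np.ndarray
    acceptor_index: int = 6  # 1-based, fixed by the 10-mer convention

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.matrix.shape != (10, 20):
            raise ValueError(
                f"PWM {self.kinase}: matrix shape {self.matrix.shape} != (10, 20)")
        if self.acceptor_index != 6:
            raise ValueError(f"PWM {self.kinase}: acceptor must be position 6")
        if np.any(self.matrix < 0):
            raise ValueError(f"PWM {self.kinase}: negative probability")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(
                f"PWM {self.kinase}: rows must sum to 1 (got {sums})")

    @property
    def acceptor_class(self) -> str:
        """'ST' or 'Y', from where the acceptor row puts its mass."""
        row = self.matrix[self.acceptor_index - 1]
        st = row[AA_INDEX["S"]] + row[AA_INDEX["T"]]
        return "ST" if st >= row[AA_INDEX["Y"]] else "Y"


# ---------------------------------------------------------------------------
# Site-table I/O
# ---------------------------------------------------------------------------

def _header_fields(species_a: str, species_b: str) -> list[str]:
    return [
        "pair_id",
        f"{species_a}.aa", f"{species_a}.p", f"{species_a}.diso",
        f"{species_b}.aa", f"{species_b}.p", f"{species_b}.diso",
    ]


def _parse_header(fields: Sequence[str]) -> tuple[str, str]:
    if len(fields) != 7 or fields[0] != "pair_id":
        raise ParseError(f"malformed site-table header: {fields!r}")
    sp = []
    for base in (1, 4):
        names = [fields[base + j].rsplit(".", 1) for j in range(3)]
        prefixes = {n[0] for n in names}
        suffixes = [n[1] if len(n) == 2 else "" for n in names]
        if len(prefixes) != 1 or suffixes != ["aa", "p", "diso"]:
            raise ParseError(f"malformed site-table header: {fields!r}")
        sp.append(names[0][0])
    if sp[0] == sp[1]:
        raise ParseError("site-table header repeats one species")
    return sp[0], sp[1]


def read_site_table(path_or_buf) -> list[OrthologAlignment]:
    """Read a per-column site table into validated alignments.

    Rows of one pair must be contiguous and in column order. Errors name
    the offending pair and row.
    """
    close = False
    if hasattr(path_or_buf, "read"):
        fh: TextIO = path_or_buf
    else:
        fh = open(path_or_buf, "rt")
        close = True
    try:
        return _read_site_table(fh)
    finally:
        if close:
            fh.close()


def _read_site_table(fh: TextIO) -> list[OrthologAlignment]:
    species_a = species_b = None
    alignments: list[OrthologAlignment] = []
    current_id: str | None = None
    cells: list[list[str]] = [[], [], [], [], [], []]
    seen: set[str] = set()

    def flush(row_no: int) -> None:
        nonlocal current_id
        if current_id is None:
            return
        try:
            alignments.append(OrthologAlignment(
                current_id, species_a, species_b,
                "".join(cells[0]), "".join(cells[3]),
                "".join(cells[1]), "".join(cells[4]),
                "".join(cells[2]), "".join(cells[5]),
            ))
        except ValueError as exc:
            raise ParseError(
                f"pair {current_id} (ending before row {row_no}): {exc}") from exc
        for c in cells:
            c.clear()
        current_id = None

    row_no = 0
    for row_no, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if species_a is None:
            species_a, species_b = _parse_header(fields)
            continue
        if len(fields) != 7:
            raise ParseError(f"row {row_no}: expected 7 fields, got {len(fields)}")
        pid = fields[0]
        if pid != current_id:
            flush(row_no)
            if pid in seen:
                raise ParseError(
                    f"pair {pid} at row {row_no}: rows are not contiguous")
            seen.add(pid)
            current_id = pid
        for j, cell in enumerate(fields[1:]):
            if len(cell) != 1:
                raise ParseError(
                    f"pair {pid} at row {row_no}: cell {cell!r} is not a "
                    "single character")
            cells[j].append(cell)
    if species_a is None:
        raise ParseError("site table has no header")
    flush(row_no + 1)
    return alignments


def write_site_table(alignments: Iterable[OrthologAlignment], path_or_buf) -> None:
    """Write alignments in the canonical site-table dialect."""
    alignments = list(alignments)
    if not alignments:
        raise ValueError("nothing to write")
    sa, sb = alignments[0].species_a_id, alignments[0].species_b_id
    for aln in alignments:
        if (aln.species_a_id, aln.species_b_id) != (sa, sb):
            raise ValueError("all alignments must share the same species pair")
    close = False
    if hasattr(path_or_buf, "write"):
        fh = path_or_buf
    else:
        fh = open(path_or_buf, "wt")
        close = True
    try:
        fh.write("\t".join(_header_fields(sa, sb)) + "\n")
        for aln in alignments:
            for i in range(len(aln)):
                fh.write("\t".join((
                    aln.pair_id,
                    aln.aa_a[i], aln.phospho_a[i], aln.diso_a[i],
                    aln.aa_b[i], aln.phospho_b[i], aln.diso_b[i],
                )) + "\n")
    finally:
        if close:
            fh.close()


def site_table_to_string(alignments: Iterable[OrthologAlignment]) -> str:
    buf = io.StringIO()
    write_site_table(alignments, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# PWM I/O
# ---------------------------------------------------------------------------

def read_pwms(path_or_buf) -> list[KinasePWM]:
    """Read one or more kinase PWM blocks from a TSV file."""
    close = False
    if hasattr(path_or_buf, "read"):
        fh = path_or_buf
    else:
        fh = open(path_or_buf, "rt")
        close = True
    try:
        lines = [ln.rstrip("\n") for ln in fh]
    finally:
        if close:
            fh.close()
    pwms: list[KinasePWM] = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith("#KINASE="):
            raise ParseError(f"PWM line {i + 1}: expected '#KINASE=<name>'")
        name = line[len("#KINASE="):].strip()
        if not name:
            raise ParseError(f"PWM line {i + 1}: empty kinase name")
        if i + 1 >= len(lines) or lines[i + 1].split("\t") != list(AA20):
            raise ParseError(
                f"PWM {name}: header must list the 20 amino acids "
                "in alphabetical order")
        rows = []
        for j in range(10):
            k = i + 2 + j
            if k >= len(lines):
                raise ParseError(f"PWM {name}: expected 10 probability rows")
            try:
                row = [float(x) for x in lines[k].split("\t")]
            except ValueError as exc:
                raise ParseError(f"PWM {name}, row {j + 1}: {exc}") from exc
            if len(row) != 20:
                raise ParseError(
                    f"PWM {name}, row {j + 1}: expected 20 values, got {len(row)}")
            rows.append(row)
        try:
            pwms.append(KinasePWM(name, np.array(rows)))
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
        i += 12
    if not pwms:
        raise ParseError("no PWM blocks found")
    return pwms


def write_pwms(pwms: Iterable[KinasePWM], path_or_buf) -> None:
    close = False
    if hasattr(path_or_buf, "write"):
        fh = path_or_buf
    else:
        fh = open(path_or_buf, "wt")
        close = True
    try:
        for pwm in pwms:
            fh.write(f"#KINASE={pwm.kinase}\n")
            fh.write("\t".join(AA20) + "\n")
            for row in pwm.matrix:
                fh.write("\t".join(format(x, ".8g") for x in row) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Peptide mapping
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Load a proteome FASTA into an id -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_peptides(
    peptides: Sequence[tuple[str, int]],
    proteome: Mapping[str, str],
    species: str = "",
) -> tuple[list[PhosphoSite], list[dict]]:
    """Map phosphopeptides onto a proteome by exact substring search.

    Each peptide is a ``(sequence, acceptor_offset)`` pair with the
    phosphoacceptor marked by its 1-based offset within the peptide.
    Matching is case-insensitive and treats I and L as distinct. A peptide
    matching exactly one protein at exactly one location yields a
    :class:`PhosphoSite`; anything ambiguous (several proteins, or several
    locations within one protein) or unmatched is dropped and reported,
    never guessed at.
    """
    prot = {pid: seq.upper() for pid, seq in proteome.items()}
    sites: list[PhosphoSite] = []
    rejected: list[dict] = []
    for pep, offset in peptides:
        pep_u = pep.upper()
        if not 1 <= offset <= len(pep_u):
            raise ValueError(
                f"acceptor offset {offset} outside peptide {pep!r}")
        if pep_u[offset - 1] not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"peptide {pep!r}: acceptor residue {pep_u[offset - 1]!r} "
                "is not S/T/Y")
        hits = [(pid, pos) for pid, seq in prot.items()
                for pos in _occurrences(seq, pep_u)]
        n_proteins = len({pid for pid, _ in hits})
        if not hits:
            rejected.append({"peptide": pep, "reason": "unmatched"})
        elif n_proteins > 1:
            rejected.append({"peptide": pep, "reason": "ambiguous"})
        elif len(hits) > 1:
            rejected.append({"peptide": pep, "reason": "ambiguous-within-protein"})
        else:
            pid, start = hits[0]
            pos = start + offset  # 0-based start + 1-based offset = 1-based site
            sites.append(PhosphoSite(pid, species, pos, pep_u[offset - 1]))
    return sites, rejected


# ---------------------------------------------------------------------------
# Placing sites onto alignments
# ---------------------------------------------------------------------------

def sites_to_columns(
    alignment: OrthologAlignment,
    sites: Iterable[PhosphoSite],
) -> OrthologAlignment:
    """Return a copy of ``alignment`` with phospho flags set from ``sites``.

    Each site's 1-based ungapped position is mapped to its alignment column
    (the bijection between ungapped positions and non-gap columns). The
    aligned residue must match the site's residue.
    """
    new_p = {
        "a": list(alignment.phospho_a),
        "b": list(alignment.phospho_b),
    }
    for site in sites:
        key = alignment._species_key(site.species)
        col = alignment.column_of(site.species, site.position)
        found = alignment.aa(site.species)[col - 1]
        if found != site.residue:
            raise MappingError(
                f"{alignment.pair_id}: site {site.protein_id}:{site.position} "
                f"expects {site.residue}, alignment has {found!r} at column {col}")
        new_p[key][col - 1] = "1"
    return replace(
        alignment,
        phospho_a="".join(new_p["a"]),
        phospho_b="".join(new_p["b"]),
    )
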