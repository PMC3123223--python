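"""Gap extraction and modified complex indel coding (MCIC).

Alignment gaps carry phylogenetic signal that plain nucleotide characters
miss.  MCIC converts each set of positionally homologous gap extents into a
standard (morphology-style) character appended to the nucleotide matrix:

* a gap extent overlapping no other extent becomes a binary
  presence/absence character;
* mutually overlapping extents (connected components of the interval
  overlap graph) become one multistate character whose states are the
  distinct extents plus a "no gap" state, with a symmetric step-cost
  matrix between states.

Terminal (leading/trailing) gap runs are incomplete sequence, not indel
events; they are flagged and coded as missing ``?``.

Two cost dialects are provided because downstream tree lengths depend on
them: ``"unit"`` (every state-to-state change costs 1) and ``"mcic"``
(no-gap <-> gap costs 1; nested extents cost 1; overlapping non-nested
extents cost 2, reflecting the minimum number of indel events required).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import MultipleAlignment, InputError

__all__ = [
    "GapEvent",
    "CodedCharacter",
    "CodedMatrix",
    "extract_gap_events",
    "mcic_code",
    "write_nexus",
    "read_nexus",
]


@dataclass(frozen=True)
class GapEvent:
    """A distinct gap extent (1-based inclusive columns) and its carriers."""

    start: int
    end: int
    members: frozenset[str]
    terminal: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GapEvent") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "GapEvent") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class CodedCharacter:
    name: str
    symbols: list[str]  # state symbols; index 0 is "no gap" by convention
    states: dict[str, str]  # sequence id -> symbol or '?'
    step_matrix: np.ndarray | None = None  # aligned to symbols
    span: tuple[int, int] | None = None  # 1-based covered columns

    def column(self, ids: list[str]) -> list[str]:
        return [self.states.get(i, "?") for i in ids]


@dataclass
class CodedMatrix:
    """Nucleotide alignment plus appended indel-derived standard characters."""

    alignment: MultipleAlignment
    coded: list[CodedCharacter] = field(default_factory=list)

    @property
    def total_characters(self) -> int:
        return self.alignment.length + len(self.coded)


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal gap runs in a row, 1-based inclusive."""
    runs = []
    start = None
    for j, c in enumerate(row, 1):
        if c == "-":
            if start is None:
                start = j
        elif start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def extract_gap_events(aln: MultipleAlignment) -> list[GapEvent]:
    """One event per distinct (start, end) gap extent.

    Terminal runs (touching column 1 or the last column) are returned with
    ``terminal=True``; downstream coding treats them as missing data.
    """
    internal: dict[tuple[int, int], set[str]] = {}
    terminal: dict[tuple[int, int], set[str]] = {}
    for sid, row in zip(aln.ids, aln.rows):
        for start, end in _gap_runs(row):
            bucket = terminal if (start == 1 or end == aln.length) else internal
            bucket.setdefault((start, end), set()).add(sid)
    events = [GapEvent(s, e, frozenset(m)) for (s, e), m in internal.items()]
    events += [GapEvent(s, e, frozenset(m), terminal=True)
               for (s, e), m in terminal.items()]
    events.sort(key=lambda ev: (ev.start, ev.end))
    return events


def _components(events: list[GapEvent]) -> list[list[GapEvent]]:
    """Connected components of the extent overlap graph (transitive chains)."""
    parent = list(range(len(events)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(events)):
        for j in range(i + 1, len(events)):
            if events[i].overlaps(events[j]):
                parent[find(i)] = find(j)
    comps: dict[int, list[GapEvent]] = {}
    for i, ev in enumerate(events):
        comps.setdefault(find(i), []).append(ev)
    return [sorted(c, key=lambda ev: (ev.start, ev.end)) for c in comps.values()]


def _step_matrix(extents: list[GapEvent], mode: str) -> np.ndarray:
    """Symmetric zero-diagonal costs over [no-gap] + extents."""
    k = len(extents) + 1
    m = np.ones((k, k), dtype=float)
    np.fill_diagonal(m, 0.0)
    if mode == "mcic":
        for i, a in enumerate(extents, start=1):
            for j, b in enumerate(extents, start=1):
                if i == j:
                    continue
                nested = a.contains(b) or b.contains(a)
                m[i, j] = 1.0 if nested else 2.0
    elif mode != "unit":
        raise InputError(f"unknown MCIC cost mode {mode!r}")
    return m


def mcic_code(aln: MultipleAlignment, cost_mode: str = "mcic") -> CodedMatrix:
    """Code internal gap extents as standard characters appended to ``aln``."""
    events = extract_gap_events(aln)
    terminal = [ev for ev in events if ev.terminal]
    internal = [ev for ev in events if not ev.terminal]
    coded: list[CodedCharacter] = []
    for comp in _components(internal):
        lo = min(ev.start for ev in comp)
        hi = max(ev.end for ev in comp)
        symbols = [str(s) for s in range(len(comp) + 1)]
        states: dict[str, str] = {}
        for sid, row in zip(aln.ids, aln.rows):
            # missing if a terminal gap run of this sequence intrudes
            if any(t.start <= hi and lo <= t.end for t in terminal if sid in t.members):
                states[sid] = "?"
                continue
            owner = next((i for i, ev in enumerate(comp, start=1)
                          if sid in ev.members), None)
            if owner is not None:
                states[sid] = str(owner)
            elif "-" in row[lo - 1:hi]:
                # gap in span but matching no coded extent (e.g. run that is
                # terminal elsewhere or sub-threshold): state undeterminable
                states[sid] = "?"
            else:
                states[sid] = "0"
        if len(comp) == 1:
            step = None  # binary presence/absence, implicit unit cost
        else:
            step = _step_matrix(comp, cost_mode)
        coded.append(CodedCharacter(
            name=f"indel_{lo}_{hi}", symbols=symbols, states=states,
            step_matrix=step, span=(lo, hi)))
    coded.sort(key=lambda c: c.span)
    return CodedMatrix(aln, coded)


# ---------------------------------------------------------------------------
# NEXUS round trip (MrBayes-style mixed datatype block + step matrices)
# ---------------------------------------------------------------------------

def _nexus_name(name: str) -> str:
    return f"'{name}'" if any(c in name for c in " ()[]{}/\\,;:=*'\"`<>-") else name


def write_nexus(cm: CodedMatrix, path: str | Path) -> None:
    aln = cm.alignment
    n_dna = aln.length
    n_total = cm.total_characters
    lines = ["#NEXUS", ""]
    lines.append("BEGIN DATA;")
    lines.append(f"    DIMENSIONS NTAX={aln.n_sequences} NCHAR={n_total};")
    if cm.coded:
        fmt = (f"    FORMAT DATATYPE=MIXED(DNA:1-{n_dna},"
               f"STANDARD:{n_dna + 1}-{n_total}) GAP=- MISSING=? INTERLEAVE=NO;")
    else:
        fmt = "    FORMAT DATATYPE=DNA GAP=- MISSING=? INTERLEAVE=NO;"
    lines.append(fmt)
    lines.append("    MATRIX")
    width = max(len(i) for i in aln.ids) + 2
    for sid, row in zip(aln.ids, aln.rows):
        coded = "".join(ch.states.get(sid, "?") for ch in cm.coded)
        lines.append(f"    {_nexus_name(sid):<{width}}{row}{coded}")
    lines.append("    ;")
    lines.append("END;")
    if cm.coded:
        lines.append("")
        lines.append("BEGIN SETS;")
        lines.append(f"    CHARSET nucleotides = 1-{n_dna};")
        lines.append(f"    CHARSET indels = {n_dna + 1}-{n_total};")
        lines.append("END;")
        steppy = [(i, ch) for i, ch in enumerate(cm.coded)
                  if ch.step_matrix is not None]
        if steppy:
            lines.append("")
            lines.append("BEGIN ASSUMPTIONS;")
            for i, ch in steppy:
                k = len(ch.symbols)
                lines.append(f"    USERTYPE step_{ch.name} (STEPMATRIX) = {k}")
                lines.append("        " + " ".join(ch.symbols))
                for r in range(k):
                    cells = [("." if r == c else
                              f"{ch.step_matrix[r, c]:g}") for c in range(k)]
                    lines.append("        " + " ".join(cells))
                lines.append("    ;")
                lines.append(
                    f"    TYPESET * indel_types = step_{ch.name}: {n_dna + 1 + i};")
            lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")


def read_nexus(path: str | Path) -> CodedMatrix:
    """Parse the NEXUS dialect written by :func:`write_nexus`."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    try:
        dims = next(ln for ln in lines if ln.upper().startswith("DIMENSIONS"))
    except StopIteration:
        raise InputError(f"{path}: no DIMENSIONS line") from None
    ntax = int(dims.upper().split("NTAX=")[1].split()[0].rstrip(";"))
    nchar = int(dims.upper().split("NCHAR=")[1].split()[0].rstrip(";"))
    fmt = next(ln for ln in lines if ln.upper().startswith("FORMAT"))
    if "MIXED" in fmt.upper():
        inner = fmt[fmt.index("(") + 1:fmt.index(")")]
        spans = {}
        for part in inner.split(","):
            dtype, rng = part.split(":")
            a, b = rng.split("-")
            spans[dtype.strip().upper()] = (int(a), int(b))
        n_dna = spans["DNA"][1]
    else:
        n_dna = nchar
    mi = lines.index(next(ln for ln in lines if ln.upper() == "MATRIX"))
    ids, dna_rows, coded_rows = [], [], []
    for ln in lines[mi + 1:]:
        if ln == ";" or ln.upper().startswith("END"):
            break
        if not ln:
            continue
        if ln.startswith("'"):
            close = ln.index("'", 1)
            name, seq = ln[1:close], ln[close + 1:].strip()
        else:
            name, seq = ln.split(None, 1)
        ids.append(name)
        dna_rows.append(seq[:n_dna])
        coded_rows.append(seq[n_dna:])
    if len(ids) != ntax:
        raise InputError(f"{path}: NTAX={ntax} but {len(ids)} matrix rows")
    aln = MultipleAlignment(ids, dna_rows)
    # step matrices
    steps: dict[str, np.ndarray] = {}
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.upper().startswith("USERTYPE"):
            name = ln.split()[1]
            k = int(ln.rstrip(";").split("=")[1].strip())
            symbols = lines[i + 1].split()
            m = np.zeros((k, k))
            for r in range(k):
                cells = lines[i + 2 + r].split()
                for c in range(k):
                    m[r, c] = 0.0 if cells[c] == "." else float(cells[c])
            steps[name] = m
            i += 2 + k
        i += 1
    coded: list[CodedCharacter] = []
    n_coded = nchar - n_dna
    for j in range(n_coded):
        states = {sid: coded_rows[r][j] for r, sid in enumerate(ids)}
        observed = sorted({s for s in states.values() if s != "?"},
                          key=lambda s: int(s))
        nstates = max((int(s) for s in observed), default=0) + 1
        symbols = [str(s) for s in range(max(nstates, 2))]
        coded.append(CodedCharacter(name=f"coded_{j + 1}", symbols=symbols,
                                    states=states, step_matrix=None))
    # reattach step matrices by position from TYPESET lines
    for ln in lines:
        if ln.upper().startswith("TYPESET"):
            rhs = ln.rstrip(";").split("=", 1)[1]
            tname, pos = rhs.split(":")
            idx = int(pos) - n_dna - 1
            coded[idx].step_matrix = steps[tname.strip()]
            coded[idx].symbols = [str(s)
                                  for s in range(len(steps[tname.strip()]))]
    return CodedMatrix(aln, coded)
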