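"""Nearest-neighbor thermodynamics for RNA secondary structures and duplexes.

The model scores a structure as a sum over its loops: helical stacks from a
6x6 table, length-indexed hairpin/bulge/internal-loop penalties with
logarithmic extrapolation, an affine multiloop term, and a terminal AU/GU
penalty charged once for every helix end (each side of a pair that is not
part of a continuous stack). Dangling ends, terminal mismatches, coaxial
stacking and special small loops are deliberately out of scope, which keeps
the intramolecular model, the duplex model and the partition function in
:mod:`srnatarget.ensemble` exactly consistent with one another.

Coordinates are 0-based internally. Display coordinates relative to a
translation start have no position 0: +1 is the A of AUG and -1 the
nucleotide before it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "GAS_CONSTANT",
    "RnaSequence",
    "SecondaryStructure",
    "EnergyParameters",
    "PAIR_TYPES",
    "pair_index",
    "parse_dotbracket",
    "structure_energy",
    "duplex_energy",
    "default_parameters",
    "load_parameters",
]

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT = 0.0019872

ALPHABET = "ACGU"

#: The six allowed pair types, written 5'-side nucleotide first.
PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")
_PAIR_INDEX = {p: k for k, p in enumerate(PAIR_TYPES)}

#: Pair types that carry the terminal AU/GU penalty at helix ends.
WEAK_PAIRS = frozenset({"AU", "UA", "GU", "UG"})

COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


def pair_index(a: str, b: str) -> int:
    """Return the table index of pair (a, b), or -1 if not pairable."""
    return _PAIR_INDEX.get(a + b, -1)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


class ValidityError(ValueError):
    """A structure or duplex violates a model invariant."""


class DotBracketError(ValueError):
    """Malformed dot-bracket text."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence.

    Parameters
    ----------
    id:
        Record identifier.
    seq:
        Residues over {A, C, G, U}. DNA-style T is converted to U on
        construction (recorded in ``converted_t``).
    start_codon_offset:
        Optional 0-based index of the A of the start codon AUG; enables
        start-codon-relative display coordinates.
    """

    id: str
    seq: str
    start_codon_offset: int | None = None
    converted_t: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        raw = self.seq.upper().replace(" ", "")
        converted = "T" in raw
        raw = raw.replace("T", "U")
        if not raw:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(raw) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-RNA characters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", raw)
        object.__setattr__(self, "converted_t", converted)
        if self.start_codon_offset is not None:
            if not 0 <= self.start_codon_offset < len(raw):
                raise ValueError(
                    f"start_codon_offset {self.start_codon_offset} outside "
                    f"sequence of length {len(raw)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def __getitem__(self, item):
        return self.seq[item]

    def to_relative(self, pos1: int) -> int:
        """Map a 1-based sequence position to start-codon-relative display
        coordinates (..., -2, -1, +1, +2, ...; +1 = A of AUG)."""
        if self.start_codon_offset is None:
            raise ValueError(f"sequence {self.id!r} has no start-codon anchor")
        anchor = self.start_codon_offset + 1  # 1-based position of the A
        return pos1 - anchor + 1 if pos1 >= anchor else pos1 - anchor

    def from_relative(self, rel: int) -> int:
        """Inverse of :meth:`to_relative`."""
        if rel == 0:
            raise ValueError("start-codon-relative coordinates have no position 0")
        if self.start_codon_offset is None:
            raise ValueError(f"sequence {self.id!r} has no start-codon anchor")
        anchor = self.start_codon_offset + 1
        return rel + anchor - 1 if rel > 0 else rel + anchor


@dataclass(frozen=True)
class SecondaryStructure:
    """A non-crossing set of intramolecular base pairs (0-based, i < j)."""

    pairs: frozenset[tuple[int, int]]

    def __init__(self, pairs: Iterable[tuple[int, int]]):
        object.__setattr__(self, "pairs", frozenset((int(i), int(j)) for i, j in pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def partner_map(self, n: int) -> list[int]:
        """Array of partners, -1 for unpaired positions."""
        part = [-1] * n
        for i, j in self.pairs:
            part[i] = j
            part[j] = i
        return part

    def validate(self, seq: RnaSequence) -> None:
        """Raise :class:`ValidityError` unless the structure is valid for seq."""
        n = len(seq)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ValidityError(f"pair ({i},{j}) outside sequence of length {n}")
            if i in seen or j in seen:
                raise ValidityError(f"position in pair ({i},{j}) is paired twice")
            seen.update((i, j))
            if pair_index(seq[i], seq[j]) < 0:
                raise ValidityError(
                    f"disallowed pair {seq[i]}{seq[j]} at ({i},{j})"
                )
            if j - i < 4:
                raise ValidityError(
                    f"hairpin closed by ({i},{j}) encloses fewer than 3 nt"
                )
        ordered = self.sorted_pairs()
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1:]:
                if k >= j:
                    break
                if i < k < j < l:
                    raise ValidityError(
                        f"crossing pairs ({i},{j}) and ({k},{l})"
                    )

    def to_dotbracket(self, n: int) -> str:
        chars = ["."] * n
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


@dataclass
class EnergyParameters:
    """Nearest-neighbor free-energy parameters at a fixed temperature.

    ``stack[p][q]`` is the stack of outer pair p = (i, j) on inner pair
    q = (i+1, j-1), indexed by :data:`PAIR_TYPES`. Loop tables are indexed
    by loop length and extrapolate logarithmically beyond their last entry
    with coefficient ``lxc``.
    """

    temperature: float
    stack: list[list[float]]
    hairpin: dict[int, float]
    bulge: dict[int, float]
    internal: dict[int, float]
    multiloop_closing: float
    multiloop_branch: float
    multiloop_unpaired: float
    terminal_AU: float
    duplex_init: float
    lxc: float
    max_loop_span: int = 30

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if len(self.stack) != 6 or any(len(r) != 6 for r in self.stack):
            raise ValueError("stack table must be 6x6")
        for name, tab in (("hairpin", self.hairpin), ("bulge", self.bulge),
                          ("internal", self.internal)):
            if not tab or any(not math.isfinite(v) for v in tab.values()):
                raise ValueError(f"{name} table empty or non-finite")

    @property
    def RT(self) -> float:
        return GAS_CONSTANT * self.temperature

    def _loop_table(self, table: dict[int, float], length: int) -> float:
        if length in table:
            return table[length]
        m = max(table)
        if length < min(table):
            raise ValidityError(f"loop of length {length} below table minimum")
        return table[m] + self.lxc * math.log(length / m)

    def hairpin_energy(self, length: int) -> float:
        if length < 3:
            raise ValidityError(f"hairpin loop of length {length} < 3")
        return self._loop_table(self.hairpin, length)

    def bulge_energy(self, length: int) -> float:
        return self._loop_table(self.bulge, length)

    def internal_energy(self, length: int) -> float:
        return self._loop_table(self.internal, length)

    def loop_energy(self, l1: int, l2: int) -> float:
        """Generic interior-loop term for side lengths (l1, l2), not a stack."""
        if l1 == 0 and l2 == 0:
            raise ValueError("stacks are scored from the stack table")
        if l1 == 0 or l2 == 0:
            return self.bulge_energy(l1 + l2)
        return self.internal_energy(l1 + l2)

    def au_penalty(self, a: str, b: str) -> float:
        return self.terminal_AU if (a + b) in WEAK_PAIRS else 0.0


def load_parameters(text: str) -> EnergyParameters:
    """Parse an :class:`EnergyParameters` from the plain-text table format
    documented in ``data/nn_params_37C.txt``."""
    constants: dict[str, float] = {}
    stack: list[list[float]] = []
    tables: dict[str, dict[int, float]] = {"hairpin": {}, "bulge": {}, "internal": {}}
    section = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            continue
        if section == "constants":
            key, _, val = line.partition("=")
            constants[key.strip()] = float(val)
        elif section == "stack":
            fields = line.split()
            if fields[0] not in _PAIR_INDEX:
                raise ValueError(f"unknown pair row {fields[0]!r} in stack table")
            stack.append([float(v) for v in fields[1:7]])
        elif section in tables:
            length, val = line.split()
            tables[section][int(length)] = float(val)
        else:
            raise ValueError(f"data line outside a known section: {line!r}")
    return EnergyParameters(
        temperature=constants["temperature"],
        stack=stack,
        hairpin=tables["hairpin"],
        bulge=tables["bulge"],
        internal=tables["internal"],
        multiloop_closing=constants["multiloop_closing"],
        multiloop_branch=constants["multiloop_branch"],
        multiloop_unpaired=constants["multiloop_unpaired"],
        terminal_AU=constants["terminal_AU"],
        duplex_init=constants["duplex_init"],
        lxc=constants["lxc"],
        max_loop_span=int(constants.get("max_loop_span", 30)),
    )


_DEFAULT_PARAMS: EnergyParameters | None = None


def default_parameters() -> EnergyParameters:
    """The shipped Turner-2004-style table at 37 C (cached)."""
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        text = (
            resources.files("srnatarget") / "data" / "nn_params_37C.txt"
        ).read_text()
        _DEFAULT_PARAMS = load_parameters(text)
    return _DEFAULT_PARAMS


def parse_dotbracket(text: str, seq: RnaSequence) -> SecondaryStructure:
    """Convert dot-bracket notation into a validated structure."""
    if len(text) != len(seq):
        raise DotBracketError(
            f"dot-bracket length {len(text)} != sequence length {len(seq)}"
        )
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise DotBracketError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise DotBracketError(f"unbalanced '(' at position {stack[-1]}")
    structure = SecondaryStructure(pairs)
    structure.validate(seq)
    return structure


def _loop_decomposition(structure: SecondaryStructure, n: int):
    """Yield (closing_pair_or_None, children) for every loop of the structure.

    ``None`` as closing pair denotes the exterior loop. Children are the
    directly enclosed pairs, in 5' to 3' order.
    """
    ordered = structure.sorted_pairs()
    # Children of each pair via an interval stack over pairs sorted by i.
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    open_stack: list[tuple[int, int]] = []
    for pair in ordered:
        while open_stack and pair[0] > open_stack[-1][1]:
            open_stack.pop()
        parent = open_stack[-1] if open_stack else None
        children.setdefault(pair, [])
        children[parent].append(pair)
        open_stack.append(pair)
    yield None, children[None]
    for pair in ordered:
        yield pair, children[pair]


def structure_energy(
    seq: RnaSequence,
    structure: SecondaryStructure,
    params: EnergyParameters | None = None,
    validate: bool = True,
) -> float:
    """Nearest-neighbor free energy (kcal/mol) of an intramolecular structure.

    The empty structure scores 0.0; the energy is additive over independent
    exterior-loop substructures.
    """
    params = params or default_parameters()
    if validate:
        structure.validate(seq)
    s = seq.seq

    def au(pair: tuple[int, int]) -> float:
        return params.au_penalty(s[pair[0]], s[pair[1]])

    energy = 0.0
    for closing, kids in _loop_decomposition(structure, len(s)):
        if closing is None:
            energy += sum(au(k) for k in kids)
            continue
        i, j = closing
        if not kids:
            energy += params.hairpin_energy(j - i - 1) + au(closing)
        elif len(kids) == 1:
            k, l = kids[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                energy += params.stack[pair_index(s[i], s[j])][pair_index(s[k], s[l])]
            else:
                energy += params.loop_energy(l1, l2) + au(closing) + au(kids[0])
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            energy += (
                params.multiloop_closing
                + params.multiloop_branch * (len(kids) + 1)
                + params.multiloop_unpaired * unpaired
                + au(closing)
                + sum(au(k) for k in kids)
            )
    return energy


def _validate_duplex_pairs(
    srna: str, mrna: str, pairs: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    ordered = sorted(pairs)
    prev_j = None
    for i, j in ordered:
        if not (0 <= i < len(srna)) or not (0 <= j < len(mrna)):
            raise ValidityError(f"duplex pair ({i},{j}) outside the sequences")
        if pair_index(srna[i], mrna[j]) < 0:
            raise ValidityError(
                f"disallowed duplex pair {srna[i]}{mrna[j]} at ({i},{j})"
            )
        if prev_j is not None and j >= prev_j:
            raise ValidityError(
                "duplex pairing must be strictly monotone (antiparallel)"
            )
        prev_j = j
    if len({i for i, _ in ordered}) != len(ordered):
        raise ValidityError("an sRNA position is paired twice in the duplex")
    return ordered


def duplex_energy(
    srna_seq: RnaSequence | str,
    mrna_seq: RnaSequence | str,
    duplex_pairs: Sequence[tuple[int, int]],
    params: EnergyParameters | None = None,
) -> float:
    """Free energy (kcal/mol) of an intermolecular duplex.

    ``duplex_pairs`` are (sRNA index, mRNA index) pairs, antiparallel: as
    the sRNA index increases the mRNA index must strictly decrease. The
    duplex-only model has stacks, bulge/interior loops and terminal AU/GU
    penalties at both ends; no multiloops. An empty pairing scores
    ``duplex_init`` only.
    """
    params = params or default_parameters()
    s = srna_seq.seq if isinstance(srna_seq, RnaSequence) else srna_seq
    m = mrna_seq.seq if isinstance(mrna_seq, RnaSequence) else mrna_seq
    ordered = _validate_duplex_pairs(s, m, duplex_pairs)
    energy = params.duplex_init
    if not ordered:
        return energy
    energy += params.au_penalty(s[ordered[0][0]], m[ordered[0][1]])
    energy += params.au_penalty(s[ordered[-1][0]], m[ordered[-1][1]])
    for (i, j), (k, l) in zip(ordered, ordered[1:]):
        l1, l2 = k - i - 1, j - l - 1
        if l1 == 0 and l2 == 0:
            energy += params.stack[pair_index(s[i], m[j])][pair_index(s[k], m[l])]
        else:
            energy += params.loop_energy(l1, l2)
    return energy
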