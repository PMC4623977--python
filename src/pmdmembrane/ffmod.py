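"""CHARMM NBFIX pair-override generation for probe–lipid repulsion.

The core trick that keeps co-solvent probes out of a lipid bilayer: the
Lennard-Jones interaction between the probe's central carbon and the lipid
acyl-chain methylene type (``CTL2``) is overridden pair-specifically — the
well depth is collapsed to 0.01 kcal/mol and the pair minimum-energy
distance inflated to 7 Å — without touching any per-type parameters.
CHARMM applies such overrides through its NBFIX section, where each line is

    TYPE_A  TYPE_B  -<epsilon>  <Rmin>

with the well depth written as a negative number.  ``rmin`` here is the
pair *inter-particle* minimum-energy distance (Rmin, not Rmin/2); emitters
for dialects expecting Rmin/2 can pass ``halve_rmin=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "NBFixOverride",
    "DEFAULT_EPSILON",
    "DEFAULT_RMIN",
    "build_overrides",
    "emit_nbfix_stream",
    "parse_nbfix_stream",
]

#: Protocol default well-depth magnitude (kcal/mol).
DEFAULT_EPSILON = 0.01
#: Protocol default pair minimum-energy inter-particle distance (Å).
DEFAULT_RMIN = 7.0

_MAX_TYPE_LEN = 8  # CHARMM atom-type field width


@dataclass(frozen=True)
class NBFixOverride:
    """One pair-specific Lennard-Jones override."""

    type_a: str
    type_b: str
    epsilon: float  # kcal/mol, magnitude (written negated)
    rmin: float     # Å, pair minimum-energy inter-particle distance

    def __post_init__(self) -> None:
        for t in (self.type_a, self.type_b):
            if not t or len(t) > _MAX_TYPE_LEN or " " in t:
                raise ValueError(f"invalid CHARMM atom type {t!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive (magnitude of well depth)")
        if self.rmin <= 0:
            raise ValueError("rmin must be positive")


def build_overrides(probe_type: str, lipid_types: Sequence[str],
                    epsilon: float = DEFAULT_EPSILON,
                    rmin: float = DEFAULT_RMIN) -> list[NBFixOverride]:
    """One override per (probe_type, lipid_type) pair at the given parameters.

    Defaults are the standard repulsion protocol: well depth 0.01 kcal/mol
    and minimum inter-particle distance 7 Å between the probe central
    carbon and each listed lipid tail type.
    """
    lipid_types = list(lipid_types)
    if len(set(lipid_types)) != len(lipid_types):
        dupes = sorted({t for t in lipid_types if lipid_types.count(t) > 1})
        raise ValueError(f"duplicate lipid types {dupes}")
    return [NBFixOverride(probe_type, lt, epsilon, rmin) for lt in lipid_types]


_HEADER = "NBFIX"


def emit_nbfix_stream(overrides: Iterable[NBFixOverride],
                      base_stream: str | None = None,
                      halve_rmin: bool = False) -> str:
    """Render overrides as a CHARMM parameter stream NBFIX section.

    When ``base_stream`` is given its content is preserved: an existing
    NBFIX section is extended in place, otherwise one is appended.  A base
    line for the same (unordered) type pair with different parameters is a
    conflict and raises ``ValueError``.

    ``halve_rmin`` writes Rmin/2 instead of the pair Rmin for force-field
    dialects that expect the half distance.
    """
    overrides = list(overrides)
    seen: dict[frozenset, NBFixOverride] = {}
    for ov in overrides:
        key = frozenset((ov.type_a, ov.type_b))
        if key in seen and seen[key] != ov:
            raise ValueError(f"conflicting overrides for pair {ov.type_a}/{ov.type_b}")
        seen[key] = ov

    def fmt(ov: NBFixOverride) -> str:
        r = ov.rmin / 2.0 if halve_rmin else ov.rmin
        return f"{ov.type_a:<8s} {ov.type_b:<8s} {-ov.epsilon:.6f} {r:.6f}"

    lines = [fmt(ov) for ov in dict.fromkeys(overrides)]

    if base_stream is None:
        body = "\n".join([_HEADER, *lines])
        return body + "\nEND\n"

    base_lines = base_stream.splitlines()
    existing = parse_nbfix_stream(base_stream) if _has_nbfix(base_lines) else []
    for old in existing:
        key = frozenset((old.type_a, old.type_b))
        if key in seen and seen[key] != old:
            raise ValueError(
                f"base stream already defines pair {old.type_a}/{old.type_b} "
                f"with different parameters"
            )
    new_lines = [fmt(ov) for ov in dict.fromkeys(overrides)
                 if frozenset((ov.type_a, ov.type_b))
                 not in {frozenset((o.type_a, o.type_b)) for o in existing}]

    if _has_nbfix(base_lines):
        out = []
        inserted = False
        for ln in base_lines:
            out.append(ln)
            if not inserted and ln.split("!")[0].strip().upper().startswith(_HEADER):
                out.extend(new_lines)
                inserted = True
        return "\n".join(out) + "\n"
    text = base_stream if base_stream.endswith("\n") else base_stream + "\n"
    return text + "\n".join([_HEADER, *new_lines]) + "\nEND\n"


def _has_nbfix(lines: Sequence[str]) -> bool:
    return any(ln.split("!")[0].strip().upper().startswith(_HEADER) for ln in lines)


_SECTION_BREAKERS = (
    "END", "BONDS", "ANGLES", "DIHEDRALS", "IMPROPERS", "IMPROPER",
    "NONBONDED", "CMAP", "ATOMS", "HBOND", "RETURN",
)


def parse_nbfix_stream(text: str) -> list[NBFixOverride]:
    """Recover the override list from a parameter stream's NBFIX section.

    Well depths are returned as magnitudes (sign stripped).  Comment lines
    (``!`` or ``*``) are ignored; a non-comment line inside the section
    with other than 4 whitespace-separated fields (or non-numeric
    parameters) raises ``ValueError`` with its 1-based line number.
    """
    overrides: list[NBFixOverride] = []
    in_section = False
    found = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        code = raw.split("!")[0].strip()
        if not code or raw.lstrip().startswith("*"):
            continue
        upper = code.upper()
        if upper.startswith(_HEADER):
            in_section = True
            found = True
            continue
        if in_section and any(upper.startswith(b) for b in _SECTION_BREAKERS):
            in_section = False
            continue
        if not in_section:
            continue
        fields = code.split()
        if len(fields) != 4:
            raise ValueError(
                f"line {lineno}: NBFIX line must have 4 fields "
                f"(TYPE_A TYPE_B -eps rmin), got {len(fields)}"
            )
        try:
            eps = float(fields[2])
            rmin = float(fields[3])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric NBFIX parameters") from exc
        overrides.append(NBFixOverride(fields[0], fields[1], abs(eps), rmin))
    if not found:
        raise ValueError("no NBFIX section in stream")
    return overrides
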