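"""Reduced nearest-neighbor free-energy model for nested RNA structures.

The model covers Watson-Crick and G.U pair stacking (Turner-1999-derived
table shipped as a TSV fixture), hairpin/bulge/internal loop initiation
penalties with Jacobson-Stockmayer extension for large loops, and a flat
multiloop penalty with a per-branch term.  No dangles, no coaxial stacking,
no terminal-AU penalty, no loop sequence bonuses: the target application is
detecting local stem-loop elements, not full Turner-model fidelity.

Energies are handled internally as integers in units of 0.1 kcal/mol so
that minimization and structure evaluation are exact and comparisons never
depend on float rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

#: Pairs the model can form (5' base, 3' base).
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

MIN_LOOP = 3  # minimum unpaired nt in a hairpin loop
MAX_INTERIOR = 30  # largest bulge/internal loop the folder will introduce

_JS_COEF = 1.08  # 1.75 * RT at 37 C, kcal/mol, for loop-size extrapolation


def can_pair(a: str, b: str) -> bool:
    return (a, b) in ALLOWED_PAIRS


def _deci(x: float) -> int:
    return round(x * 10)


@dataclass(frozen=True)
class EnergyModel:
    """Immutable parameter set; all accessors return deci-kcal/mol ints."""

    stack_table: dict[tuple[str, str], int]
    hairpin_table: dict[int, int]
    bulge_table: dict[int, int]
    internal_table: dict[int, int]
    multi_init: int
    multi_branch: int

    def stack(self, outer: str, inner: str) -> int:
        return self.stack_table[(outer, inner)]

    def _extend(self, table: dict[int, int], n: int) -> int:
        n_max = max(table)
        if n <= n_max:
            return table[n]
        return table[n_max] + _deci(_JS_COEF * math.log(n / n_max))

    def hairpin(self, n: int) -> int:
        if n < MIN_LOOP:
            raise ValueError(f"hairpin loop of {n} nt below minimum {MIN_LOOP}")
        return self._extend(self.hairpin_table, n)

    def bulge(self, n: int) -> int:
        return self._extend(self.bulge_table, n)

    def internal(self, n: int) -> int:
        if n < 2:
            raise ValueError("internal loop needs >= 1 unpaired nt per side")
        return self._extend(self.internal_table, n)

    def interior_loop(self, d5: int, d3: int, outer: str, inner: str) -> int:
        """Energy of the loop between two pairs with d5/d3 unpaired nt on the
        5'/3' sides: a stack, a bulge, or an internal loop."""
        if d5 == 0 and d3 == 0:
            return self.stack(outer, inner)
        if d5 == 0 or d3 == 0:
            return self.bulge(d5 + d3)
        return self.internal(d5 + d3)


def _load_params() -> EnergyModel:
    pkg = resources.files(__package__) / "params"
    stack: dict[tuple[str, str], int] = {}
    for line in (pkg / "stacking.tsv").read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        outer, inner, dg = line.split("\t")
        stack[(outer, inner)] = _deci(float(dg))
    tables: dict[str, dict[int, int]] = {"hairpin": {}, "bulge": {}, "internal": {}}
    multi = {}
    for line in (pkg / "loops.tsv").read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        kind, size, dg = line.split("\t")
        if kind.startswith("multiloop"):
            multi[kind] = _deci(float(dg))
        else:
            tables[kind][int(size)] = _deci(float(dg))
    return EnergyModel(
        stack_table=stack,
        hairpin_table=tables["hairpin"],
        bulge_table=tables["bulge"],
        internal_table=tables["internal"],
        multi_init=multi["multiloop_init"],
        multi_branch=multi["multiloop_branch"],
    )


_DEFAULT: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_params()
    return _DEFAULT


def pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    """0-based (i, j) pairs; raises on unbalanced or crossing-free violation."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx + 1}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return sorted(pairs)


def evaluate_deci(seq: str, db: str, model: EnergyModel | None = None) -> int:
    """Free energy of a given nested structure, by loop decomposition.

    Independent of the folding recursions: walks the pair list, classifies
    every loop (hairpin / stack / bulge / internal / multiloop) and sums the
    corresponding parameters.  External-loop bases are free.
    """
    model = model or default_model()
    if len(seq) != len(db):
        raise ValueError("sequence and structure lengths differ")
    pairs = pairs_from_dotbracket(db)
    pairmap = {i: j for i, j in pairs}
    for i, j in pairs:
        if not can_pair(seq[i], seq[j]):
            raise ValueError(
                f"disallowed pair {seq[i]}{seq[j]} at positions {i + 1},{j + 1}"
            )
    total = 0
    for i, j in pairs:
        # children: pairs directly enclosed by (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in pairmap:
                children.append((k, pairmap[k]))
                k = pairmap[k] + 1
            else:
                k += 1
        outer = seq[i] + seq[j]
        if not children:
            total += model.hairpin(j - i - 1)
        elif len(children) == 1:
            (k, l) = children[0]
            inner = seq[k] + seq[l]
            total += model.interior_loop(k - i - 1, j - l - 1, outer, inner)
        else:
            total += model.multi_init + model.multi_branch * (len(children) + 1)
    return total


def evaluate(seq: str, db: str, model: EnergyModel | None = None) -> float:
    """Free energy in kcal/mol of a given structure."""
    return evaluate_deci(seq, db, model) / 10.0
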