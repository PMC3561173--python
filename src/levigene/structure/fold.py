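"""Minimum-free-energy folding of short RNA windows (Zuker-style DP).

The recursions mirror the loop decomposition of :mod:`.energy` exactly, so
the DP optimum equals the minimum of :func:`~levigene.structure.energy.evaluate`
over all nested structures (verified against exhaustive enumeration in the
test suite).  Objective: minimize free energy; among co-optimal structures
maximize the number of pairs; the traceback then resolves any remaining ties
by a fixed scan order, so output is fully deterministic.  Windows are capped
at 400 nt — the pipeline only ever folds local windows (UTRs, start-codon
contexts), never whole genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..seqio import normalize_rna
from .energy import (
    EnergyModel,
    MAX_INTERIOR,
    MIN_LOOP,
    can_pair,
    default_model,
    evaluate_deci,
    pairs_from_dotbracket,
)

MAX_WINDOW = 400

# DP values are (deci_energy, -n_pairs) tuples; lexicographic comparison
# implements "min energy, then max pairs" and is preserved under addition.
_INF = (10**9, 0)


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure with its free-energy estimate."""

    sequence: str
    pairing: str  # dot-bracket, same length as sequence
    energy: float  # kcal/mol

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.pairing):
            raise ValueError("sequence/pairing length mismatch")
        for i, j in pairs_from_dotbracket(self.pairing):
            if not can_pair(self.sequence[i], self.sequence[j]):
                raise ValueError(
                    f"disallowed pair {self.sequence[i]}{self.sequence[j]} "
                    f"at {i + 1},{j + 1}"
                )

    @property
    def n_pairs(self) -> int:
        return self.pairing.count("(")

    @property
    def pair_map(self) -> dict[int, int]:
        """0-based symmetric pair map."""
        pm: dict[int, int] = {}
        for i, j in pairs_from_dotbracket(self.pairing):
            pm[i] = j
            pm[j] = i
        return pm

    def to_vienna(self) -> str:
        return f"{self.sequence}\n{self.pairing} ({self.energy:.1f})"


def _tadd(*vals: tuple[int, int]) -> tuple[int, int]:
    e = 0
    p = 0
    for v in vals:
        e += v[0]
        p += v[1]
    return (e, p)


def fold_mfe(window: str, model: EnergyModel | None = None) -> SecondaryStructure:
    """Fold a window into its MFE nested structure under the reduced model.

    Returns the all-unpaired structure with energy 0 when no structure has
    negative free energy (so energy == 0 iff there are no pairs).
    """
    model = model or default_model()
    seq = normalize_rna(window)
    n = len(seq)
    if n > MAX_WINDOW:
        raise ValueError(f"window of {n} nt exceeds maximum {MAX_WINDOW}")

    pairable = [
        [
            (j - i - 1 >= MIN_LOOP and can_pair(seq[i], seq[j]))
            for j in range(n)
        ]
        for i in range(n)
    ]

    V = [[_INF] * n for _ in range(n)]
    WM = [[_INF] * n for _ in range(n)]
    mb = (model.multi_branch, 0)

    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V(i,j): optimal structure closed by pair (i,j) ---
            if pairable[i][j]:
                outer = seq[i] + seq[j]
                best = (model.hairpin(j - i - 1), -1)
                kmax = min(i + 1 + MAX_INTERIOR, j - MIN_LOOP - 1)
                for k in range(i + 1, kmax + 1):
                    d5 = k - i - 1
                    Vk = V[k]
                    lmin = max(k + MIN_LOOP + 1, j - 1 - (MAX_INTERIOR - d5))
                    for l in range(lmin, j):
                        vkl = Vk[l]
                        if vkl is _INF:
                            continue
                        loop_e = model.interior_loop(
                            d5, j - l - 1, outer, seq[k] + seq[l]
                        )
                        cand = (loop_e + vkl[0], vkl[1] - 1)
                        if cand < best:
                            best = cand
                    # multiloop closure: (i,j) closes >= 2 branches
                close = model.multi_init + model.multi_branch
                WMrow = WM[i + 1]
                for k in range(i + 2, j - 1):
                    a = WMrow[k]
                    if a is _INF:
                        continue
                    b = WM[k + 1][j - 1]
                    if b is _INF:
                        continue
                    cand = (close + a[0] + b[0], a[1] + b[1] - 1)
                    if cand < best:
                        best = cand
                V[i][j] = best
            # --- WM(i,j): >=1 branch inside a multiloop, unpaired free ---
            best = _INF
            if WM[i + 1][j] is not _INF:
                best = WM[i + 1][j]
            if WM[i][j - 1] is not _INF and WM[i][j - 1] < best:
                best = WM[i][j - 1]
            if V[i][j] is not _INF:
                cand = _tadd(V[i][j], mb)
                if cand < best:
                    best = cand
            WMrow = WM[i]
            for k in range(i + 1, j + 1):
                a = WMrow[k - 1]
                if a is _INF:
                    continue
                b = WM[k][j]
                if b is _INF:
                    continue
                cand = _tadd(a, b)
                if cand < best:
                    best = cand
            WM[i][j] = best

    # --- external loop ---
    W = [(0, 0)] * (n + 1)  # W[j+1] covers prefix [0..j]
    for j in range(n):
        best = W[j]
        for i in range(0, j):
            if V[i][j] is _INF:
                continue
            cand = _tadd(W[i], V[i][j])
            if cand < best:
                best = cand
        W[j + 1] = best

    if W[n][0] >= 0:
        return SecondaryStructure(seq, "." * n, 0.0)

    db = ["."] * n
    _traceback(seq, model, V, WM, W, n, db)
    struct = "".join(db)
    energy = evaluate_deci(seq, struct, model)
    assert energy == W[n][0], "traceback/energy mismatch"
    return SecondaryStructure(seq, struct, energy / 10.0)


def _traceback(seq, model, V, WM, W, n, db) -> None:
    tasks: list[tuple] = [("W", n - 1)]
    mb = model.multi_branch
    while tasks:
        task = tasks.pop()
        if task[0] == "W":
            j = task[1]
            if j < 0:
                continue
            target = W[j + 1]
            done = False
            for i in range(0, j):
                if V[i][j] is not _INF and _tadd(W[i], V[i][j]) == target:
                    tasks.append(("W", i - 1))
                    tasks.append(("V", i, j))
                    done = True
                    break
            if not done:
                tasks.append(("W", j - 1))
        elif task[0] == "V":
            i, j = task[1], task[2]
            db[i] = "("
            db[j] = ")"
            target = V[i][j]
            if target == (model.hairpin(j - i - 1), -1):
                continue
            outer = seq[i] + seq[j]
            found = False
            kmax = min(i + 1 + MAX_INTERIOR, j - MIN_LOOP - 1)
            for k in range(i + 1, kmax + 1):
                d5 = k - i - 1
                lmin = max(k + MIN_LOOP + 1, j - 1 - (MAX_INTERIOR - d5))
                for l in range(lmin, j):
                    if V[k][l] is _INF:
                        continue
                    loop_e = model.interior_loop(d5, j - l - 1, outer, seq[k] + seq[l])
                    if (loop_e + V[k][l][0], V[k][l][1] - 1) == target:
                        tasks.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            close = model.multi_init + mb
            for k in range(i + 2, j - 1):
                a = WM[i + 1][k]
                b = WM[k + 1][j - 1]
                if a is _INF or b is _INF:
                    continue
                if (close + a[0] + b[0], a[1] + b[1] - 1) == target:
                    tasks.append(("WM", i + 1, k))
                    tasks.append(("WM", k + 1, j - 1))
                    found = True
                    break
            assert found, "V traceback failed"
        else:  # WM
            i, j = task[1], task[2]
            target = WM[i][j]
            if V[i][j] is not _INF and _tadd(V[i][j], (mb, 0)) == target:
                tasks.append(("V", i, j))
                continue
            if WM[i + 1][j] == target:
                tasks.append(("WM", i + 1, j))
                continue
            if WM[i][j - 1] == target:
                tasks.append(("WM", i, j - 1))
                continue
            found = False
            for k in range(i + 1, j + 1):
                a = WM[i][k - 1]
                b = WM[k][j]
                if a is _INF or b is _INF:
                    continue
                if _tadd(a, b) == target:
                    tasks.append(("WM", i, k - 1))
                    tasks.append(("WM", k, j))
                    found = True
                    break
            assert found, "WM traceback failed"
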