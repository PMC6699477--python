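"""Minimum-free-energy RNA secondary structure for conserved loci.

A simplified nearest-neighbor Zuker-style dynamic program: Watson-Crick and
GU pairs, stacking energies by pair-class table, length-indexed hairpin /
bulge / internal-loop penalties, and a linear multiloop penalty.  Pseudoknots
are excluded, lonely pairs allowed, and the minimum hairpin loop is 3 nt.
The empty structure has energy 0, so the MFE is never positive; a conserved
locus is an sRNA candidate when its MFE is strictly below 0 kcal/mol.

The energy table deliberately differs from full Turner parameters (and from
external folding tools), so candidate *counts* on real data are approximate;
the MFE < 0 candidacy rule is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

INF = float("inf")

CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}


def _default_stack() -> dict[tuple[str, str], float]:
    """Stacking energy (kcal/mol) of an outer pair on an inner pair."""
    cls = {"GC": "GC", "CG": "GC", "AU": "AU", "UA": "AU", "GU": "GU", "UG": "GU"}
    class_default = {
        ("GC", "GC"): -2.9,
        ("GC", "AU"): -2.1, ("AU", "GC"): -2.1,
        ("GC", "GU"): -1.5, ("GU", "GC"): -1.5,
        ("AU", "AU"): -1.1,
        ("AU", "GU"): -0.5, ("GU", "AU"): -0.5,
        ("GU", "GU"): -0.4,
    }
    table = {}
    for outer in CANONICAL:
        for inner in CANONICAL:
            table[(outer, inner)] = class_default[(cls[outer], cls[inner])]
    table[("GC", "CG")] = -3.3
    table[("CG", "GC")] = -2.4
    return table


@dataclass
class EnergyModel:
    stack: dict[tuple[str, str], float] = field(default_factory=_default_stack)
    hairpin_base: float = 4.0
    hairpin_per_nt: float = 0.05  # beyond the 3-nt minimum
    bulge_base: float = 3.5
    bulge_per_nt: float = 0.2
    internal_base: float = 3.0
    internal_per_nt: float = 0.15
    multi_closing: float = 4.0
    multi_branch: float = 0.4  # per branch, closing pair included
    min_hairpin: int = 3
    max_loop: int = 10  # cap on bulge/internal unpaired total

    def hairpin(self, size: int) -> float:
        return self.hairpin_base + self.hairpin_per_nt * (size - self.min_hairpin)

    def bulge(self, size: int) -> float:
        return self.bulge_base + self.bulge_per_nt * size

    def internal(self, l1: int, l2: int) -> float:
        return self.internal_base + self.internal_per_nt * (l1 + l2)

    def multiloop(self, branches: int) -> float:
        return self.multi_closing + self.multi_branch * branches


@dataclass
class FoldResult:
    seq_id: str
    sequence: str  # RNA alphabet
    structure: str  # dot-bracket
    mfe: float
    pairs: list[tuple[int, int]]

    @property
    def is_srna_candidate(self) -> bool:
        return self.mfe < 0


def _to_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    return seq


def structure_energy(seq: str, pairs: Sequence[tuple[int, int]], model: EnergyModel | None = None) -> float:
    """Energy of an explicit structure under the model, by loop decomposition.

    Validates the structure: canonical pairs only, non-crossing, hairpin
    loops of at least ``min_hairpin`` unpaired nt.
    """
    model = model or EnergyModel()
    rna = _to_rna(seq)
    plist = sorted((min(i, j), max(i, j)) for i, j in pairs)
    partner: dict[int, int] = {}
    for i, j in plist:
        if i == j or i in partner or j in partner:
            raise ValueError("base in two pairs")
        if rna[i] + rna[j] not in CANONICAL:
            raise ValueError(f"non-canonical pair {rna[i]}{rna[j]} at ({i},{j})")
        partner[i] = j
        partner[j] = i
    for (i, j), (p, q) in zip(plist, plist[1:]):
        if i < p < j < q:
            raise ValueError("crossing pairs (pseudoknot)")

    def children(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        """Pairs directly enclosed by (i, j) and the loop's unpaired count."""
        kids = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        return kids, unpaired

    energy = 0.0
    for i, j in plist:
        kids, unpaired = children(i, j)
        if not kids:
            if unpaired < model.min_hairpin:
                raise ValueError(f"hairpin loop of {unpaired} nt at ({i},{j})")
            energy += model.hairpin(unpaired)
        elif len(kids) == 1:
            p, q = kids[0]
            l1, l2 = p - i - 1, j - q - 1
            if l1 == 0 and l2 == 0:
                energy += model.stack[(rna[i] + rna[j], rna[p] + rna[q])]
            elif l1 == 0 or l2 == 0:
                energy += model.bulge(l1 + l2)
            else:
                energy += model.internal(l1, l2)
        else:
            energy += model.multiloop(len(kids) + 1)
    return energy


def fold(sequence: str, model: EnergyModel | None = None, seq_id: str = "seq") -> FoldResult:
    """MFE structure by dynamic programming (see module docstring).

    Ties in the traceback prefer a paired option, then the smaller closing
    index, so output is deterministic.
    """
    model = model or EnergyModel()
    rna = _to_rna(sequence)
    n = len(rna)
    if n == 0:
        raise ValueError("empty sequence")

    def pairable(i: int, j: int) -> bool:
        return rna[i] + rna[j] in CANONICAL and j - i - 1 >= model.min_hairpin

    V = [[INF] * n for _ in range(n)]
    M = [[INF] * n for _ in range(n)]  # >=1 branch, unpaired free

    for span in range(model.min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable(i, j):
                best = model.hairpin(j - i - 1)
                if pairable(i + 1, j - 1) and V[i + 1][j - 1] < INF:
                    e = V[i + 1][j - 1] + model.stack[(rna[i] + rna[j], rna[i + 1] + rna[j - 1])]
                    if e < best:
                        best = e
                for p in range(i + 1, j):
                    l1 = p - i - 1
                    if l1 > model.max_loop:
                        break
                    for q in range(j - 1, p, -1):
                        l2 = j - q - 1
                        if l2 > model.max_loop or l1 + l2 > model.max_loop:
                            break
                        if l1 + l2 == 0 or V[p][q] == INF:
                            continue
                        pen = model.bulge(l1 + l2) if (l1 == 0 or l2 == 0) else model.internal(l1, l2)
                        e = V[p][q] + pen
                        if e < best:
                            best = e
                for k in range(i + 2, j - 1):
                    if M[i + 1][k] < INF and M[k + 1][j - 1] < INF:
                        # branch terms for the enclosed helices are inside M;
                        # add the closing pair's branch and the loop constant
                        e = M[i + 1][k] + M[k + 1][j - 1] + model.multi_closing + model.multi_branch
                        if e < best:
                            best = e
                V[i][j] = best
            # M
            cands = []
            if V[i][j] < INF:
                cands.append(V[i][j] + model.multi_branch)
            if i + 1 <= j:
                cands.append(M[i + 1][j])
                cands.append(M[i][j - 1])
            for k in range(i + 1, j):
                if M[i][k] < INF and M[k + 1][j] < INF:
                    cands.append(M[i][k] + M[k + 1][j])
            M[i][j] = min(cands) if cands else INF

    W = [0.0] * (n + 1)  # W[j] = best energy of rna[:j]
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j - 1):
            if V[i][j - 1] < INF:
                e = W[i] + V[i][j - 1]
                if e < best:
                    best = e
        W[j] = best
    mfe = W[n]

    # traceback
    pairs: list[tuple[int, int]] = []
    eps = 1e-9

    def tb_V(i: int, j: int) -> None:
        pairs.append((i, j))
        e = V[i][j]
        if pairable(i + 1, j - 1) and V[i + 1][j - 1] < INF:
            if abs(V[i + 1][j - 1] + model.stack[(rna[i] + rna[j], rna[i + 1] + rna[j - 1])] - e) < eps:
                tb_V(i + 1, j - 1)
                return
        for p in range(i + 1, j):
            l1 = p - i - 1
            if l1 > model.max_loop:
                break
            for q in range(j - 1, p, -1):
                l2 = j - q - 1
                if l2 > model.max_loop or l1 + l2 > model.max_loop:
                    break
                if l1 + l2 == 0 or V[p][q] == INF:
                    continue
                pen = model.bulge(l1 + l2) if (l1 == 0 or l2 == 0) else model.internal(l1, l2)
                if abs(V[p][q] + pen - e) < eps:
                    tb_V(p, q)
                    return
        for k in range(i + 2, j - 1):
            if M[i + 1][k] < INF and M[k + 1][j - 1] < INF:
                if abs(M[i + 1][k] + M[k + 1][j - 1] + model.multi_closing + model.multi_branch - e) < eps:
                    tb_M(i + 1, k)
                    tb_M(k + 1, j - 1)
                    return
        # hairpin: nothing to add

    def tb_M(i: int, j: int) -> None:
        e = M[i][j]
        if V[i][j] < INF and abs(V[i][j] + model.multi_branch - e) < eps:
            tb_V(i, j)
            return
        for k in range(i + 1, j):
            if M[i][k] < INF and M[k + 1][j] < INF and abs(M[i][k] + M[k + 1][j] - e) < eps:
                tb_M(i, k)
                tb_M(k + 1, j)
                return
        if i + 1 <= j and abs(M[i + 1][j] - e) < eps:
            tb_M(i + 1, j)
            return
        if abs(M[i][j - 1] - e) < eps:
            tb_M(i, j - 1)
            return
        raise AssertionError("traceback failure in M")

    j = n
    while j > 0:
        target = W[j]
        advanced = False
        for i in range(0, j - 1):  # prefer paired, smaller closing index
            if V[i][j - 1] < INF and abs(W[i] + V[i][j - 1] - target) < eps:
                tb_V(i, j - 1)
                j = i
                advanced = True
                break
        if not advanced:
            j -= 1

    pairs.sort()
    db = ["."] * n
    for i, jj in pairs:
        db[i], db[jj] = "(", ")"
    return FoldResult(seq_id=seq_id, sequence=rna, structure="".join(db), mfe=round(mfe, 6), pairs=pairs)


def srna_screen(loci, min_len: int = 21, model: EnergyModel | None = None) -> list[FoldResult]:
    """Fold each conserved-locus consensus of length >= ``min_len``; results
    flag sRNA candidates (MFE < 0)."""
    model = model or EnergyModel()
    out = []
    for lc in loci:
        if lc.length < min_len:
            continue
        out.append(fold(lc.consensus, model, seq_id=f"{lc.group_id}:{lc.col_start}-{lc.col_end}"))
    return out


def write_folds_tsv(results: Sequence[FoldResult], path: str | Path) -> None:
    lines = ["id\tlength\tmfe\tcandidate"]
    for r in results:
        lines.append(f"{r.seq_id}\t{len(r.sequence)}\t{r.mfe:.2f}\t{int(r.is_srna_candidate)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dotbracket(results: Sequence[FoldResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in results:
            fh.write(f">{r.seq_id} mfe={r.mfe:.2f}\n{r.sequence}\n{r.structure}\n")


def write_ct(result: FoldResult, path: str | Path) -> None:
    partner = {i: j for i, j in result.pairs}
    partner.update({j: i for i, j in result.pairs})
    n = len(result.sequence)
    lines = [f"{n} {result.seq_id} mfe={result.mfe:.2f}"]
    for i, base in enumerate(result.sequence):
        lines.append(f"{i + 1} {base} {i} {i + 2 if i + 1 < n else 0} {partner.get(i, -1) + 1} {i + 1}")
    Path(path).write_text("\n".join(lines) + "\n")
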