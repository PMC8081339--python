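"""RNA secondary-structure free energies.

Two sources are supported: parsing the text output of an external
minimum-free-energy folder (RNAfold-format blocks), and a built-in
weighted-base-pair dynamic program so the pipeline runs end to end with no
external binary. The built-in model is Nussinov-style — pair energies
GC = -3, AU = -2, GU = -1 kcal/mol on a stand-in scale, hairpin loops of at
least ``min_loop`` unpaired bases, no pseudoknots — a monotone proxy for
thermodynamic folding free energy, not a Turner-model implementation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqfeatures import normalize_rna

__all__ = [
    "StructureResult",
    "PAIR_ENERGY",
    "parse_rnafold_output",
    "predict_mfe_standin",
    "fold_many",
]

#: stand-in stacking-free pair energies, kcal/mol
PAIR_ENERGY: dict[frozenset[str], float] = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}

#: transcripts longer than this are excluded from folding by default
MAX_FOLD_LENGTH = 10_000


@dataclass(frozen=True)
class StructureResult:
    """Dot-bracket structure and free energy for one sequence."""

    sequence_id: str
    dotbracket: str
    energy: float

    def __post_init__(self) -> None:
        depth = 0
        for ch in self.dotbracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket")
            elif ch != ".":
                raise ValueError(f"invalid dot-bracket character {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket")
        if self.energy > 0:
            raise ValueError("free energy must be <= 0")


_ENERGY_RE = re.compile(r"^([.()]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def parse_rnafold_output(text: str) -> list[StructureResult]:
    """Parse RNAfold-format text blocks.

    Each block is a ``>`` header line, the sequence line, and a structure
    line ending in the energy in parentheses, e.g. ``((...)). (-3.40)``.
    Unparsable blocks raise with their block index.
    """
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    out = []
    i = 0
    block = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"block {block}: expected '>' header, got {lines[i]!r}")
        seq_id = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"block {block}: truncated")
        m = _ENERGY_RE.match(lines[i + 2].replace("−", "-"))
        if m is None:
            raise ValueError(f"block {block}: unparsable structure line "
                             f"{lines[i + 2]!r}")
        dotbracket, energy = m.group(1), float(m.group(2))
        if len(dotbracket) != len(lines[i + 1].strip()):
            raise ValueError(f"block {block}: structure/sequence length mismatch")
        try:
            out.append(StructureResult(seq_id, dotbracket, energy))
        except ValueError as exc:
            raise ValueError(f"block {block}: {exc}") from exc
        i += 3
        block += 1
    return out


def _pair_energy(a: str, b: str) -> float:
    return PAIR_ENERGY.get(frozenset((a, b)), 0.0)


def predict_mfe_standin(sequence: str, min_loop: int = 3,
                        sequence_id: str = "") -> StructureResult:
    """Optimal weighted-base-pair structure by dynamic programming.

    E[i][j] is the minimum energy of subsequence [i, j]; pairs (i, j)
    require j - i > min_loop; recurrence considers i unpaired or i paired
    with any admissible k. Deterministic; traceback emits a consistent
    dot-bracket.
    """
    seq = normalize_rna(sequence)
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid bases: {sorted(bad)}")
    n = len(seq)
    E = np.zeros((n + 1, n + 1))  # E[i, j] over half-open [i, j)
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = E[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j):
                e = _pair_energy(seq[i], seq[k])
                if e < 0:
                    cand = e + E[i + 1, k] + E[k + 1, j]
                    if cand < best:
                        best = cand
            E[i, j] = best

    struct = ["."] * n
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 2:
            continue
        if E[i, j] == E[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j):
            e = _pair_energy(seq[i], seq[k])
            if e < 0 and E[i, j] == e + E[i + 1, k] + E[k + 1, j]:
                struct[i], struct[k] = "(", ")"
                stack.append((i + 1, k))
                stack.append((k + 1, j))
                break
    return StructureResult(sequence_id, "".join(struct), float(E[0, n]))


def fold_many(records, max_length: int = MAX_FOLD_LENGTH,
              min_loop: int = 3) -> pd.DataFrame:
    """Fold each record with the stand-in, skipping over-length sequences.

    Returns a table (id, length, energy, energy_per_nt, dotbracket); both
    raw and per-nt energies are emitted since screening may want either.
    """
    rows = []
    for rec in records:
        seq = getattr(rec, "sequence", None) or str(rec)
        rid = getattr(rec, "transcript_id", "") or ""
        if len(seq) >= max_length:
            continue
        res = predict_mfe_standin(seq, min_loop=min_loop, sequence_id=rid)
        rows.append({"transcript_id": rid, "length": len(seq),
                     "energy": res.energy,
                     "energy_per_nt": res.energy / len(seq),
                     "dotbracket": res.dotbracket})
    return pd.DataFrame(rows)
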