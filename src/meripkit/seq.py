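"""Nucleotide-sequence helpers: complements, IUPAC degeneracy, shuffles."""

from __future__ import annotations

import re

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC degenerate nucleotide codes (DNA alphabet; U is read as T).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def iupac_to_regex(pattern: str) -> str:
    """Expand an IUPAC pattern (e.g. DRACH) into a character-class regex."""
    parts = []
    for ch in pattern.upper().replace("U", "T"):
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        allowed = IUPAC[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return "".join(parts)


def matches_iupac(seq: str, pattern: str) -> bool:
    return re.fullmatch(iupac_to_regex(pattern), seq.upper()) is not None


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide composition.

    Altschul–Erickson edge shuffling: treat each dinucleotide as an edge
    of a multigraph over the residues, pick for every non-terminal vertex
    a random last outgoing edge such that those last edges form a tree
    into the terminal vertex, shuffle the remaining edges, and walk the
    Eulerian path. The result has the same first residue, last residue
    and dinucleotide counts as the input.
    """
    if len(seq) < 3:
        return seq
    seq = seq.upper()
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    for _ in range(1000):
        chosen = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last}
        # the chosen last-edges must all lead (transitively) to the terminal
        ok = True
        for v in chosen:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in chosen:
                    ok = False
                    break
                seen.add(cur)
                cur = chosen[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for DNA
        raise RuntimeError("dinucleotide shuffle failed to converge")
    shuffled: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v != last:
            rest.remove(chosen[v])
        perm = rng.permutation(len(rest))
        rest = [rest[i] for i in perm]
        if v != last:
            rest.append(chosen[v])
        shuffled[v] = rest
    out = [seq[0]]
    ptr = {v: 0 for v in shuffled}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
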