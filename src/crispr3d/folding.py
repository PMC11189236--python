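"""Minimum-free-energy backends for sgRNA secondary structure.

The bundled backend is a deliberately compact Zuker-style dynamic program
over nested structures: Watson-Crick and GU wobble pairs, approximate
Turner-style stacking energies, tabulated hairpin-loop initiation (minimum
loop of 3), and a linear penalty for bulge/interior loops (multibranch
loops are not scored — on 20-nt guides they are essentially unreachable).
It is deterministic and dependency-free; absolute energies are coarser than
a full Turner-model fold, but sign and ordering (structured vs unstructured
guides) are what the downstream feature consumes.

``rnafold_mfe`` shells out to ViennaRNA's RNAfold when a full
nearest-neighbor model is wanted.
"""

from __future__ import annotations

import subprocess

from .errors import BackendError, InputError

__all__ = ["simple_mfe", "rnafold_mfe", "mfe"]

_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}

# approximate Turner-style 5'->3' stack energies, kcal/mol at 37C,
# keyed by (closing pair, stacked pair)
_STACK = {
    ("AU", "AU"): -0.9, ("AU", "UA"): -1.1, ("UA", "AU"): -1.3, ("UA", "UA"): -0.9,
    ("AU", "GC"): -2.2, ("AU", "CG"): -2.1, ("UA", "GC"): -2.4, ("UA", "CG"): -2.1,
    ("GC", "AU"): -2.1, ("GC", "UA"): -2.2, ("CG", "AU"): -2.1, ("CG", "UA"): -2.4,
    ("GC", "GC"): -3.3, ("GC", "CG"): -3.4, ("CG", "GC"): -2.4, ("CG", "CG"): -3.3,
    ("GU", "GU"): -0.5, ("UG", "UG"): -0.5, ("GU", "UG"): -0.6, ("UG", "GU"): -0.6,
}
_WOBBLE_DEFAULT = -1.0  # mixed stacks involving one GU pair

_HAIRPIN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5}
_INTERIOR_INIT = 3.5
_INTERIOR_PER_NT = 0.4
_MAX_INTERIOR = 10
_MIN_HAIRPIN = 3


def _stack_energy(p1: str, p2: str) -> float:
    e = _STACK.get((p1, p2))
    if e is None:
        e = _WOBBLE_DEFAULT
    return e


def _hairpin_energy(size: int) -> float:
    if size in _HAIRPIN:
        return _HAIRPIN[size]
    import math

    return 5.5 + 1.08 * math.log(size / 8.0)


def simple_mfe(rna: str) -> float:
    """Minimum free energy (kcal/mol, <= 0) of an RNA under the bundled model.

    An unpairable sequence (e.g. poly-A) folds to the open chain at 0.0.
    """
    s = rna.upper().replace("T", "U")
    if any(b not in "ACGU" for b in s):
        raise InputError(f"non-ACGU base in RNA sequence {rna!r}")
    n = len(s)
    INF = float("inf")
    V = [[INF] * n for _ in range(n)]  # energy given (i,j) paired
    for span in range(_MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if s[i] + s[j] not in _PAIRS:
                continue
            best = _hairpin_energy(j - i - 1)
            pij = s[i] + s[j]
            if s[i + 1] + s[j - 1] in _PAIRS and V[i + 1][j - 1] < INF:
                best = min(best, V[i + 1][j - 1] + _stack_energy(pij, s[i + 1] + s[j - 1]))
            for k in range(i + 1, j - _MIN_HAIRPIN - 1):
                for l in range(k + _MIN_HAIRPIN + 1, j):
                    loop = (k - i - 1) + (j - l - 1)
                    if loop == 0 or loop > _MAX_INTERIOR:
                        continue
                    if V[k][l] < INF:
                        best = min(best, V[k][l] + _INTERIOR_INIT + _INTERIOR_PER_NT * loop)
            V[i][j] = best
    # external loop: best combination of non-overlapping closed structures
    W = [0.0] * (n + 1)
    for j in range(1, n + 1):
        W[j] = W[j - 1]
        for i in range(0, j):
            if V[i][j - 1] < INF:
                W[j] = min(W[j], W[i] + V[i][j - 1])
    return min(0.0, W[n])


def rnafold_mfe(rna: str) -> float:
    """MFE from ViennaRNA's RNAfold CLI (full Turner model)."""
    s = rna.upper().replace("T", "U")
    try:
        out = subprocess.run(
            ["RNAfold", "--noPS"], input=s + "\n", capture_output=True, text=True, check=True
        ).stdout
    except (OSError, subprocess.CalledProcessError) as e:
        raise BackendError(f"RNAfold backend failed: {e}") from e
    try:
        last = out.strip().splitlines()[-1]
        return float(last.rsplit("(", 1)[1].rstrip(")").strip())
    except (IndexError, ValueError) as e:
        raise BackendError(f"could not parse RNAfold output: {out!r}") from e


_BACKENDS = {"simple": simple_mfe, "rnafold": rnafold_mfe}


def mfe(rna: str, backend: str = "simple") -> float:
    """Dispatch to a folding backend ("simple" bundled DP or "rnafold")."""
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise BackendError(f"unknown folding backend {backend!r}") from None
    return fn(rna)
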