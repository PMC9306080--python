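"""Synthetic 4860-pattern substructure library (Klekota–Roth-shaped).

The protein-space stage represents each ligand by per-pattern substructure
match counts over a fixed library of 4860 SMARTS queries, the dimensionality
of the Klekota–Roth fingerprint.  The original Klekota–Roth SMARTS list is
distributed inside PaDEL/CDK and is not redistributable here, so this module
generates a *synthetic* library of exactly 4860 valid, distinct SMARTS
patterns with the same shape and contract: a fixed, deterministic ordering
with stable indices 0..4859, every pattern a compilable substructure query.

Construction (fully deterministic, no randomness):

1. a curated block of common organic functional-group patterns;
2. all bonded atom pairs over a fixed organic alphabet;
3. bonded linear triples over the same alphabet, reverse-deduplicated
   (``C-N=O`` and ``O=N-C`` denote the same query; only the
   lexicographically smaller orientation is kept);
4. small aromatic-ring and fused motifs.

The concatenation is truncated to exactly 4860 entries.
"""

from __future__ import annotations

from functools import lru_cache

LIBRARY_SIZE = 4860
LIBRARY_VERSION = "synthetic-kr-shape-1.0"

# Organic subset alphabet: aliphatic then aromatic symbols, fixed order.
_ALIPHATIC = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B"]
_AROMATIC = ["c", "n", "o", "s"]
_BONDS = ["-", "=", "#", ":"]

# Curated functional-group block (standard organic chemistry motifs).
_FUNCTIONAL_GROUPS = [
    "[OX2H]",                      # hydroxyl
    "[CX3]=[OX1]",                 # carbonyl
    "[CX3](=O)[OX2H1]",            # carboxylic acid
    "[CX3](=O)[OX1-]",             # carboxylate
    "[CX3](=O)[OX2][#6]",          # ester
    "[CX3](=O)[NX3]",              # amide
    "[NX3;H2]",                    # primary amine
    "[NX3;H1]([#6])[#6]",          # secondary amine
    "[NX3]([#6])([#6])[#6]",       # tertiary amine
    "[NX4+]",                      # ammonium
    "[NX3][CX3]=[NX2]",            # amidine
    "[NX3][CX3](=[NX2])[NX3]",     # guanidine
    "[CX2]#[NX1]",                 # nitrile
    "[NX2]=[OX1]",                 # nitroso
    "[NX3](=O)=O",                 # nitro (charge-separated form matched too)
    "[SX2H]",                      # thiol
    "[SX2]([#6])[#6]",             # thioether
    "[SX4](=O)(=O)[NX3]",          # sulfonamide
    "[SX4](=O)(=O)[OX2H]",         # sulfonic acid
    "[SX3](=O)[#6]",               # sulfoxide
    "[PX4](=O)([OX2])[OX2]",       # phosphate ester
    "[F,Cl,Br,I]",                 # any halogen
    "[CX4][F,Cl,Br,I]",            # alkyl halide
    "c[F,Cl,Br,I]",                # aryl halide
    "[CX3]=[CX3]",                 # alkene
    "[CX2]#[CX2]",                 # alkyne
    "[cX3]1[cX3][cX3][cX3][cX3][cX3]1",  # benzene
    "c1ccc2ccccc2c1",              # naphthalene
    "c1ccc2[nH]ccc2c1",            # indole-like
    "c1cnc2ncccc2c1",              # naphthyridine-like
    "c1ccc2ncccc2c1",              # quinoline
    "c1ccc2c(c1)ncn2",             # benzimidazole core
    "c1cnc[nH]1",                  # imidazole
    "c1ccoc1",                     # furan
    "c1ccsc1",                     # thiophene
    "c1cc[nH]c1",                  # pyrrole
    "c1ccncc1",                    # pyridine
    "c1cncnc1",                    # pyrimidine
    "c1cnncc1",                    # pyridazine-like
    "c1cocn1",                     # oxazole
    "c1cscn1",                     # thiazole
    "c1nnc[nH]1",                  # triazole
    "c1ncnc2[nH]cnc12",            # purine
    "C1CCCCC1",                    # cyclohexane
    "C1CCCC1",                     # cyclopentane
    "C1CCNCC1",                    # piperidine
    "C1CCOC1",                     # tetrahydrofuran
    "C1CNCCN1",                    # piperazine
    "C1COCCN1",                    # morpholine
    "[OX2]([#6])[#6]",             # ether
    "[CX3H1]=O",                   # aldehyde
    "[#6][CX3](=O)[#6]",           # ketone
    "[NX3][NX3]",                  # hydrazine
    "[NX2]=[NX2]",                 # azo
    "[OX2][OX2]",                  # peroxide
    "[#6]=[NX2][OX2H]",            # oxime
    "[NX3][OX2H]",                 # hydroxylamine
    "[CX3](=S)[NX3]",              # thioamide
    "[SX2][SX2]",                  # disulfide
    "[CX4H3]",                     # methyl
]


def _pairs() -> list[str]:
    out = []
    for b in _BONDS:
        symbols = _AROMATIC if b == ":" else _ALIPHATIC + _AROMATIC
        for i, a1 in enumerate(symbols):
            for a2 in symbols[i:]:
                out.append(f"{a1}{b}{a2}")
    return out


def _triples() -> list[str]:
    out, seen = [], set()
    symbols = _ALIPHATIC + _AROMATIC
    for a1 in symbols:
        for b1 in _BONDS:
            for a2 in symbols:
                for b2 in _BONDS:
                    for a3 in symbols:
                        if ":" in (b1, b2) and not (
                            (b1 != ":" or (a1 in _AROMATIC and a2 in _AROMATIC))
                            and (b2 != ":" or (a2 in _AROMATIC and a3 in _AROMATIC))
                        ):
                            continue
                        fwd = f"{a1}{b1}{a2}{b2}{a3}"
                        rev = f"{a3}{b2}{a2}{b1}{a1}"
                        key = min(fwd, rev)
                        if key not in seen:
                            seen.add(key)
                            out.append(key)
    return out


@lru_cache(maxsize=1)
def generate_patterns() -> tuple[str, ...]:
    """Return the full ordered library of exactly 4860 distinct SMARTS."""
    pool: list[str] = []
    seen: set[str] = set()
    for block in (_FUNCTIONAL_GROUPS, _pairs(), _triples()):
        for p in block:
            if p not in seen:
                seen.add(p)
                pool.append(p)
    if len(pool) < LIBRARY_SIZE:  # pragma: no cover - construction guarantee
        raise RuntimeError(f"pattern pool too small: {len(pool)} < {LIBRARY_SIZE}")
    return tuple(pool[:LIBRARY_SIZE])
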