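"""Recording-solution compositions and a simple speciation helper.

Solutions are entered as salt recipes (mM of each compound as weighed in) and
expanded to dissolved ionic species for the Henderson calculation:

- strong salts dissociate to their nominal ions;
- weak acids carry a fixed fractional charge at pH 7.2 via
  Henderson-Hasselbalch (HEPES pKa 7.5 -> 0.33 anionic; 4-AP pKa 9.2 ->
  ~0.99 cationic); EGTA is entered as the di-anion dominant near pH 7.2;
- chelated nucleotide complexes (MgATP, the GTP of NaGTP) and neutral
  osmolytes (glucose, mannitol, sucrose, picrotoxin) are excluded from the
  junction calculation;
- following the entry convention of the patch-clamp junction-potential
  calculators this module is validated against, the *nominal* recipe ions are
  used as-is: the small additional cation from pH titration (CsOH/KOH) is not
  added by default, though :func:`dissociate` can balance the net charge with
  a stated titration cation when asked.

The four compositions used by the bundled presets are the printed
voltage-clamp and current-clamp pipette/bath solutions for acute thalamic
slice recordings at 33-35 C.
"""

from __future__ import annotations

from .traces import SolutionComposition

#: anionic fraction of HEPES at pH 7.2 (pKa 7.5)
F_HEPES = 1.0 / (1.0 + 10.0 ** (7.5 - 7.2))
#: cationic fraction of 4-aminopyridine at pH 7.2 (pKa ~9.2)
F_4AP = 1.0 / (1.0 + 10.0 ** (7.2 - 9.2))

#: compound -> list of (ion name, charge, stoichiometry); None drops a moiety
SALTS: dict = {
    "NaCl": [("Na", 1, 1), ("Cl", -1, 1)],
    "KCl": [("K", 1, 1), ("Cl", -1, 1)],
    "CsCl": [("Cs", 1, 1), ("Cl", -1, 1)],
    "TEA-Cl": [("TEA", 1, 1), ("Cl", -1, 1)],
    "CaCl2": [("Ca", 2, 1), ("Cl", -1, 2)],
    "MgCl2": [("Mg", 2, 1), ("Cl", -1, 2)],
    "NaHCO3": [("Na", 1, 1), ("HCO3", -1, 1)],
    "NaH2PO4": [("Na", 1, 1), ("H2PO4", -1, 1)],
    "K-gluconate": [("K", 1, 1), ("gluconate", -1, 1)],
    "Cs-methanesulfonate": [("Cs", 1, 1), ("methanesulfonate", -1, 1)],
    "HEPES": [("HEPES", -1, F_HEPES)],
    "EGTA": [("EGTA", -2, 1)],
    "4-AP": [("4AP", 1, F_4AP)],
    "kynurenic acid": [("kynurenate", -1, 1)],
    # chelated complexes / neutral osmolytes: no junction contribution
    "MgATP": [],
    "NaGTP": [("Na", 1, 1)],
    "glucose": [],
    "mannitol": [],
    "sucrose": [],
    "picrotoxin": [],
}


def dissociate(
    recipe: dict, ph_adjust_cation: str | None = None, name: str = ""
) -> SolutionComposition:
    """Expand a salt recipe (compound -> mM) into dissolved ionic species.

    When ``ph_adjust_cation`` is given (e.g. ``"Cs"`` for titration with
    CsOH), that cation is added at the concentration needed to balance the
    net charge of the modeled species, emulating the titration step.
    """
    species: dict = {}
    for compound, mM in recipe.items():
        if compound not in SALTS:
            raise KeyError(f"unknown compound {compound!r}")
        for ion, z, stoich in SALTS[compound]:
            key = (ion, z)
            species[key] = species.get(key, 0.0) + mM * stoich
    if ph_adjust_cation is not None:
        net = sum(z * c for (ion, z), c in species.items())
        if net < 0:
            key = (ph_adjust_cation, 1)
            species[key] = species.get(key, 0.0) + (-net)
    return SolutionComposition(
        species=[(ion, z, c) for (ion, z), c in sorted(species.items()) if c > 0],
        name=name,
    )


def vc_pipette() -> SolutionComposition:
    """Cs-methanesulfonate voltage-clamp intracellular solution (pH 7.2, CsOH)."""
    return dissociate(
        {
            "Cs-methanesulfonate": 120.0,
            "HEPES": 10.0,
            "MgCl2": 0.5,
            "CaCl2": 1.0,
            "TEA-Cl": 10.0,
            "4-AP": 5.0,
            "EGTA": 11.0,
            "MgATP": 4.0,
            "NaGTP": 0.5,
        },
        name="vc_pipette",
    )


def vc_bath() -> SolutionComposition:
    """TEA-Cl-based voltage-clamp recording (bath) solution."""
    return dissociate(
        {
            "TEA-Cl": 126.0,
            "KCl": 2.5,
            "NaHCO3": 26.0,
            "NaH2PO4": 1.25,
            "CaCl2": 2.0,
            "MgCl2": 2.0,
            "glucose": 10.0,
            "kynurenic acid": 1.0,
            "picrotoxin": 0.1,
        },
        name="vc_bath",
    )


def cc_pipette() -> SolutionComposition:
    """K-gluconate current-clamp intracellular solution (pH 7.2, KOH)."""
    return dissociate(
        {
            "K-gluconate": 120.0,
            "HEPES": 10.0,
            "MgCl2": 1.0,
            "CaCl2": 1.0,
            "KCl": 11.0,
            "EGTA": 11.0,
            "MgATP": 4.0,
            "NaGTP": 0.5,
        },
        name="cc_pipette",
    )


def cc_bath() -> SolutionComposition:
    """NaCl-based current-clamp recording (bath) solution."""
    return dissociate(
        {
            "NaCl": 126.0,
            "KCl": 2.5,
            "NaHCO3": 26.0,
            "NaH2PO4": 1.25,
            "CaCl2": 2.0,
            "MgCl2": 2.0,
            "glucose": 10.0,
            "kynurenic acid": 1.0,
            "picrotoxin": 0.1,
        },
        name="cc_bath",
    )
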