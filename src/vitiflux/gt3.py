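"""Curated reconstruction of heterotrophic grape-cell (GT3) metabolism.

The network couples central carbon and nitrogen metabolism (glycolysis,
TCA cycle, oxidative pentose-phosphate pathway, starch and sucrose
metabolism, nitrate assimilation) to the phenylpropanoid/flavonoid
pathway via phenylalanine, with explicit energy and redox cofactors
(ATP/ADP/AMP, NAD(H), NADP(H), FAD(H2)) balanced as internal species.

Conventions:

* Fluxes are in mmol per g dry weight per day.
* Several multi-step segments are lumped into single reactions
  (e.g. GAPDH+PGK, aconitase+IDH, SDH+fumarase, the post-shikimate
  steps to phenylalanine); each lump conserves carbon, phosphate and
  nitrogen exactly, so the network passes the stoichiometric
  consistency test.
* Oxidative phosphorylation is split by electron donor into Vnrj1
  (NADH) and Vnrj2 (FADH2). Both fluxes are expressed in ATP units:
  Vnrj1 oxidizes 1/p_o_nadh mol NADH per mol ATP synthesized, so that
  flux(Vnrj1) + flux(Vnrj2) equals the ATP-synthesis rate derived from
  respiration measurements.
* Three 2-oxoglutarate-dependent dioxygenase steps of the flavonoid
  branch (Vdhq: F3H context, Vflav: flavonol synthase, Vanthoc:
  anthocyanidin synthase context) consume alpha-ketoglutarate and
  release succinate, linking pigment synthesis to the TCA cycle.
* Biosynthetic outputs (cell wall, protein, lipids, nucleotides and the
  four phenolic end products) are lumped "overall" reactions with
  configurable composition; accumulated solutes (malate, sugars, free
  amino acids) are simple accumulation exchanges into storage pools.
* Storage/medium pools are external metabolites; everything else,
  including all cofactors, is internal and therefore balanced.

Exactly 33 non-exchange reactions are irreversible; see
``docs/methods.md`` for the list and the reasoning behind each lump.
"""

from __future__ import annotations

from .model import Metabolite, Reaction, StoichiometricNetwork

__all__ = ["build_gt3_network", "GT3_MEASURED_EXCHANGES", "AKG_ID", "COFACTOR_IDS"]

AKG_ID = "akg"

COFACTOR_IDS = (
    "atp", "adp", "amp",
    "nad", "nadh", "nadp", "nadph", "fad", "fadh2",
)

#: reaction ids whose rates are fixed from measured accumulation data
#: (the measured exchange set of the study design: 8 accumulated solutes,
#: 4 phenolic end products, 4 biomass syntheses, plus starch).
GT3_MEASURED_EXCHANGES = (
    "Vac-mal", "Vac-glc", "Vac-fru", "Vac-suc",
    "Vac-Glu", "Vac-Asp", "Vac-Ala", "Vac-Phe",
    "Vanthoc", "Vflav", "Vtannins", "Vstilb",
    "Vcw", "Vprotein", "Vdag", "Vnucleotides",
    "Vstarch",
)

#: default protein composition: equal-molar over the modeled amino acids.
DEFAULT_PROTEIN_COMPOSITION = {"glu": 0.25, "asp": 0.25, "ala": 0.25, "phe": 0.25}

#: ATP cost of polymerizing one amino acid into protein (mol ATP / mol AA).
PROTEIN_ATP_COST = 4.3


def _metabolites() -> list[Metabolite]:
    cyt, vac, mit, pla, ext = "cytosol", "vacuole", "mitochondrion", "plastid", "medium"
    I, E = "internal", "external"

    def m(mid, name, role=I, tag=cyt, cof=False):
        return Metabolite(id=mid, name=name, role=role, compartment_tag=tag,
                          is_cofactor=cof)

    return [
        # --- medium / boundary pools -----------------------------------
        m("glc_e", "glucose (medium)", E, ext),
        m("fru_e", "fructose (medium)", E, ext),
        m("no3_e", "nitrate (medium)", E, ext),
        m("pi_e", "inorganic phosphate (medium)", E, ext),
        m("co2_e", "carbon dioxide (off-gas)", E, ext),
        # storage / biomass sinks
        m("mal_v", "malate (vacuolar store)", E, vac),
        m("glc_v", "glucose (vacuolar store)", E, vac),
        m("fru_v", "fructose (vacuolar store)", E, vac),
        m("suc_v", "sucrose (vacuolar store)", E, vac),
        m("glu_v", "free glutamate pool", E, vac),
        m("asp_v", "free aspartate pool", E, vac),
        m("ala_v", "free alanine pool", E, vac),
        m("phe_v", "free phenylalanine pool", E, vac),
        m("anthocyanin", "anthocyanins (end product)", E, vac),
        m("flavonol", "flavonols (end product)", E, vac),
        m("tannin", "condensed tannins (end product)", E, vac),
        m("stilbene", "stilbenes (end product)", E, vac),
        m("cellwall", "cell-wall polysaccharide", E, "wall"),
        m("protein", "total protein", E, cyt),
        m("dag", "diacylglycerol lipid", E, "membrane"),
        m("nucleotide", "nucleic acids (DNA+RNA)", E, "nucleus"),
        m("starch", "starch granule", E, pla),
        # --- sugars & glycolysis ---------------------------------------
        m("glc", "glucose"),
        m("fru", "fructose"),
        m("g6p", "glucose 6-phosphate"),
        m("f6p", "fructose 6-phosphate"),
        m("fbp", "fructose 1,6-bisphosphate"),
        m("g1p", "glucose 1-phosphate"),
        m("tp", "triose phosphate (GAP/DHAP)"),
        m("pga", "3-phosphoglycerate"),
        m("pep", "phosphoenolpyruvate"),
        m("pyr", "pyruvate"),
        m("accoa", "acetyl-CoA (acetyl moiety)"),
        m("sucr", "sucrose"),
        m("udpg", "UDP-glucose"),
        m("utp", "UTP"),
        m("udp", "UDP"),
        # --- TCA & anaplerosis -----------------------------------------
        m("oaa", "oxaloacetate", tag=mit),
        m("cit", "citrate", tag=mit),
        m("akg", "alpha-ketoglutarate", tag=mit),
        m("succ", "succinate", tag=mit),
        m("mal", "malate", tag=mit),
        # --- pentose phosphate pathway ---------------------------------
        m("ru5p", "ribulose 5-phosphate", tag=pla),
        m("r5p", "ribose 5-phosphate", tag=pla),
        m("x5p", "xylulose 5-phosphate", tag=pla),
        m("s7p", "sedoheptulose 7-phosphate", tag=pla),
        m("e4p", "erythrose 4-phosphate", tag=pla),
        # --- nitrogen ---------------------------------------------------
        m("no3", "nitrate"),
        m("nh4", "ammonium"),
        m("glu", "glutamate"),
        m("gln", "glutamine"),
        m("asp", "aspartate"),
        m("ala", "alanine"),
        m("phe", "phenylalanine"),
        # --- shikimate & phenylpropanoid/flavonoid ----------------------
        m("shk", "shikimate", tag=pla),
        m("cinn", "trans-cinnamate"),
        m("coucoa", "4-coumaroyl-CoA (coumaroyl moiety)"),
        m("malcoa", "malonyl-CoA (malonyl moiety)"),
        m("nar", "naringenin"),
        m("dhq", "dihydroquercetin"),
        m("lcc", "leucocyanidin"),
        # --- gases, phosphates, cofactors -------------------------------
        m("co2", "carbon dioxide"),
        m("pi", "inorganic phosphate"),
        m("ppi", "pyrophosphate"),
        m("atp", "ATP", cof=True),
        m("adp", "ADP", cof=True),
        m("amp", "AMP", cof=True),
        m("nad", "NAD+", cof=True, tag=mit),
        m("nadh", "NADH", cof=True, tag=mit),
        m("nadp", "NADP+", cof=True),
        m("nadph", "NADPH", cof=True),
        m("fad", "FAD", cof=True, tag=mit),
        m("fadh2", "FADH2", cof=True, tag=mit),
    ]


def build_gt3_network(
    p_o_nadh: float = 2.5,
    p_o_fadh2: float = 1.5,
    protein_composition: dict | None = None,
    protein_atp_cost: float = PROTEIN_ATP_COST,
) -> StoichiometricNetwork:
    """Build the curated GT3 grape-cell network.

    Parameters
    ----------
    p_o_nadh, p_o_fadh2:
        Effective P/O ratios: mol ATP synthesized per mol NADH (resp.
        FADH2) oxidized by the respiratory chain. Textbook defaults 2.5
        and 1.5.
    protein_composition:
        Molar fractions of the modeled amino acids in bulk protein
        (default equal-molar over glu/asp/ala/phe); must sum to 1.
    protein_atp_cost:
        ATP per peptide bond (activation + ribosome), default 4.3.
    """
    comp = dict(DEFAULT_PROTEIN_COMPOSITION if protein_composition is None
                else protein_composition)
    if abs(sum(comp.values()) - 1.0) > 1e-9:
        raise ValueError("protein composition fractions must sum to 1")

    def rxn(rid, name, stoich, rev=False, kind="internal", cap=None):
        return Reaction(id=rid, name=name, stoichiometry=stoich,
                        reversible=rev, capacity=cap, kind=kind)

    inv_n = 1.0 / p_o_nadh
    inv_f = 1.0 / p_o_fadh2

    reactions = [
        # ===== uptake exchanges =========================================
        rxn("Vglc-up", "glucose uptake", {"glc_e": -1, "glc": 1}, kind="exchange"),
        rxn("Vfru-up", "fructose uptake", {"fru_e": -1, "fru": 1}, kind="exchange"),
        rxn("Vno3-up", "nitrate uptake", {"no3_e": -1, "no3": 1}, kind="exchange"),
        rxn("Vpi-up", "phosphate uptake", {"pi_e": -1, "pi": 1}, kind="exchange"),
        rxn("Vco2-out", "CO2 release", {"co2": -1, "co2_e": 1}, kind="exchange"),
        # ===== glycolysis / sucrose / starch ============================
        rxn("Vhk-glc", "glucokinase", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1}),
        rxn("Vhk-fru", "fructokinase", {"fru": -1, "atp": -1, "f6p": 1, "adp": 1}),
        rxn("Vpgi", "phosphoglucose isomerase", {"g6p": -1, "f6p": 1}, rev=True),
        rxn("Vpgm", "phosphoglucomutase", {"g6p": -1, "g1p": 1}, rev=True),
        rxn("Vugp", "UDP-glucose pyrophosphorylase",
            {"g1p": -1, "utp": -1, "udpg": 1, "ppi": 1}, rev=True),
        rxn("Vudk", "UDP kinase (NDK)",
            {"udp": -1, "atp": -1, "utp": 1, "adp": 1}, rev=True),
        rxn("Vppa", "inorganic pyrophosphatase", {"ppi": -1, "pi": 2}),
        rxn("Vpfk", "ATP-phosphofructokinase",
            {"f6p": -1, "atp": -1, "fbp": 1, "adp": 1}),
        rxn("Vpfp", "PPi-phosphofructokinase",
            {"f6p": -1, "ppi": -1, "fbp": 1, "pi": 1}, rev=True),
        rxn("Vald", "aldolase + triose-P isomerase", {"fbp": -1, "tp": 2}, rev=True),
        rxn("Vgapdh", "GAPDH + phosphoglycerate kinase",
            {"tp": -1, "nad": -1, "adp": -1, "pi": -1,
             "pga": 1, "nadh": 1, "atp": 1}, rev=True),
        rxn("Veno", "phosphoglycerate mutase + enolase",
            {"pga": -1, "pep": 1}, rev=True),
        rxn("Vpk", "pyruvate kinase",
            {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}),
        rxn("Vsps", "sucrose-phosphate synthase + phosphatase",
            {"udpg": -1, "f6p": -1, "sucr": 1, "udp": 1, "pi": 1}),
        rxn("Vstarch", "starch synthesis (AGPase + starch synthase)",
            {"g1p": -1, "atp": -1, "starch": 1, "adp": 1, "ppi": 1},
            kind="overall"),
        # ===== TCA cycle & anaplerosis ==================================
        rxn("Vpdh", "pyruvate dehydrogenase",
            {"pyr": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1}),
        rxn("Vcs", "citrate synthase", {"accoa": -1, "oaa": -1, "cit": 1}),
        rxn("Vidh", "aconitase + isocitrate dehydrogenase",
            {"cit": -1, "nad": -1, "akg": 1, "co2": 1, "nadh": 1}),
        rxn("Vkgdh", "2-oxoglutarate dehydrogenase + succinyl-CoA synthetase",
            {"akg": -1, "nad": -1, "adp": -1, "pi": -1,
             "succ": 1, "co2": 1, "nadh": 1, "atp": 1}),
        rxn("Vsdh", "succinate dehydrogenase + fumarase",
            {"succ": -1, "fad": -1, "mal": 1, "fadh2": 1}, rev=True),
        rxn("Vmdh", "malate dehydrogenase",
            {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1}, rev=True),
        rxn("Vme", "NADP-malic enzyme",
            {"mal": -1, "nadp": -1, "pyr": 1, "co2": 1, "nadph": 1}),
        rxn("Vpepc", "PEP carboxylase",
            {"pep": -1, "co2": -1, "oaa": 1, "pi": 1}),
        # ===== oxidative pentose phosphate pathway ======================
        rxn("Vg6pdh", "G6P dehydrogenase + 6PG dehydrogenase",
            {"g6p": -1, "nadp": -2, "ru5p": 1, "co2": 1, "nadph": 2}),
        rxn("Vrpi", "ribose-5-P isomerase", {"ru5p": -1, "r5p": 1}, rev=True),
        rxn("Vrpe", "ribulose-5-P epimerase", {"ru5p": -1, "x5p": 1}, rev=True),
        rxn("Vtk1", "transketolase 1",
            {"x5p": -1, "r5p": -1, "s7p": 1, "tp": 1}, rev=True),
        rxn("Vta", "transaldolase",
            {"s7p": -1, "tp": -1, "e4p": 1, "f6p": 1}, rev=True),
        rxn("Vtk2", "transketolase 2",
            {"x5p": -1, "e4p": -1, "f6p": 1, "tp": 1}, rev=True),
        # ===== nitrogen assimilation ====================================
        rxn("Vnr", "nitrate + nitrite reductase (lumped)",
            {"no3": -1, "nadh": -1, "nadph": -3,
             "nh4": 1, "nad": 1, "nadp": 3}),
        rxn("Vgs", "glutamine synthetase",
            {"glu": -1, "nh4": -1, "atp": -1, "gln": 1, "adp": 1, "pi": 1}),
        rxn("Vgogat", "glutamate synthase (NADPH-GOGAT)",
            {"gln": -1, "akg": -1, "nadph": -1, "glu": 2, "nadp": 1}),
        rxn("Vaat", "aspartate aminotransferase",
            {"glu": -1, "oaa": -1, "akg": 1, "asp": 1}, rev=True),
        rxn("Valat", "alanine aminotransferase",
            {"glu": -1, "pyr": -1, "akg": 1, "ala": 1}, rev=True),
        # ===== shikimate & phenylpropanoid ==============================
        rxn("Vshik", "DAHP synthase .. shikimate dehydrogenase (lumped)",
            {"pep": -1, "e4p": -1, "nadph": -1,
             "shk": 1, "nadp": 1, "pi": 2}),
        rxn("Vphe-syn", "shikimate -> phenylalanine (lumped, via arogenate)",
            {"shk": -1, "pep": -1, "atp": -1, "glu": -1,
             "phe": 1, "akg": 1, "adp": 1, "pi": 2, "co2": 1}),
        rxn("Vpal", "phenylalanine ammonia-lyase",
            {"phe": -1, "cinn": 1, "nh4": 1}),
        rxn("Vcoum", "C4H + 4-coumarate:CoA ligase (lumped)",
            {"cinn": -1, "nadph": -1, "atp": -1,
             "coucoa": 1, "nadp": 1, "amp": 1, "ppi": 1}),
        rxn("Vmacl", "acetyl-CoA carboxylase (malonyl-CoA supply)",
            {"accoa": -1, "co2": -1, "atp": -1,
             "malcoa": 1, "adp": 1, "pi": 1}),
        rxn("Vnar", "chalcone synthase + isomerase (naringenin)",
            {"coucoa": -1, "malcoa": -3, "nar": 1, "co2": 3}, rev=True),
        rxn("Vdhq", "flavanone 3b-hydroxylase + F3'H (dihydroquercetin)",
            {"nar": -1, "akg": -1, "nadph": -1,
             "dhq": 1, "succ": 1, "co2": 1, "nadp": 1}, rev=True),
        rxn("Vlcc", "dihydroflavonol 4-reductase (leucocyanidin)",
            {"dhq": -1, "nadph": -1, "lcc": 1, "nadp": 1}, rev=True),
        # ===== oxidative phosphorylation & energy housekeeping ==========
        rxn("Vnrj1", "oxidative phosphorylation, NADH-linked (ATP units)",
            {"nadh": -inv_n, "adp": -1, "pi": -1, "nad": inv_n, "atp": 1}),
        rxn("Vnrj2", "oxidative phosphorylation, FADH2-linked (ATP units)",
            {"fadh2": -inv_f, "adp": -1, "pi": -1, "fad": inv_f, "atp": 1}),
        rxn("Vadk", "adenylate kinase", {"adp": -2, "atp": 1, "amp": 1}, rev=True),
        rxn("Vnga-ATPm", "non-growth-associated ATP maintenance",
            {"atp": -1, "adp": 1, "pi": 1}, kind="maintenance"),
        # ===== phenolic end products (overall) ==========================
        rxn("Vanthoc", "anthocyanidin synthase + UFGT (anthocyanins)",
            {"lcc": -1, "akg": -1, "udpg": -1,
             "anthocyanin": 1, "succ": 1, "co2": 1, "udp": 1}, kind="overall"),
        rxn("Vflav", "flavonol synthase (flavonols)",
            {"dhq": -1, "akg": -1, "flavonol": 1, "succ": 1, "co2": 1},
            kind="overall"),
        rxn("Vtannins", "LAR/ANR + polymerization (condensed tannins)",
            {"lcc": -1, "nadph": -1, "tannin": 1, "nadp": 1}, kind="overall"),
        rxn("Vstilb", "stilbene synthase (resveratrol)",
            {"coucoa": -1, "malcoa": -3, "stilbene": 1, "co2": 4}, kind="overall"),
        # ===== biomass syntheses (overall) ==============================
        rxn("Vcw", "cell-wall polysaccharide synthesis",
            {"udpg": -1, "cellwall": 1, "udp": 1}, kind="overall"),
        rxn("Vprotein", "protein synthesis (per mol amino acid)",
            {**{aa: -frac for aa, frac in sorted(comp.items()) if frac},
             "atp": -protein_atp_cost, "protein": 1,
             "adp": protein_atp_cost, "pi": protein_atp_cost}, kind="overall"),
        rxn("Vdag", "fatty acid + diacylglycerol synthesis",
            {"tp": -1, "accoa": -16, "nadph": -28, "atp": -14, "nadh": -1,
             "dag": 1, "nadp": 28, "adp": 14, "pi": 15, "nad": 1},
            kind="overall"),
        rxn("Vnucleotides", "nucleotide (DNA+RNA) synthesis",
            {"r5p": -1, "gln": -2, "asp": -1, "atp": -5,
             "nucleotide": 1, "glu": 2, "adp": 5, "pi": 5, "co2": 1},
            kind="overall"),
        # ===== accumulation exchanges ===================================
        rxn("Vac-mal", "malate accumulation", {"mal": -1, "mal_v": 1},
            kind="exchange"),
        rxn("Vac-glc", "glucose accumulation", {"glc": -1, "glc_v": 1},
            kind="exchange"),
        rxn("Vac-fru", "fructose accumulation", {"fru": -1, "fru_v": 1},
            kind="exchange"),
        rxn("Vac-suc", "sucrose accumulation", {"sucr": -1, "suc_v": 1},
            kind="exchange"),
        rxn("Vac-Glu", "free glutamate accumulation", {"glu": -1, "glu_v": 1},
            kind="exchange"),
        rxn("Vac-Asp", "free aspartate accumulation", {"asp": -1, "asp_v": 1},
            kind="exchange"),
        rxn("Vac-Ala", "free alanine accumulation", {"ala": -1, "ala_v": 1},
            kind="exchange"),
        rxn("Vac-Phe", "free phenylalanine accumulation", {"phe": -1, "phe_v": 1},
            kind="exchange"),
    ]

    return StoichiometricNetwork(
        metabolites=_metabolites(),
        reactions=reactions,
        provenance=(
            "vitiflux GT3 curated reconstruction v1 "
            f"(P/O NADH={p_o_nadh}, FADH2={p_o_fadh2}); "
            "a user-supplied SBML model takes precedence over this built-in"
        ),
    )
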