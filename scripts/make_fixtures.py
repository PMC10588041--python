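"""Regenerate the packaged network fixture TSVs (deterministic, no RNG).

Writes src/fibrenmf/data/{reactions.tsv, metabolites.tsv, constraints_synthetic.tsv}.

The KO memberships of reactions 1..68 and the 33 GH/PL family names follow the
published fibre-degradation selection; the substrate/product topology is a
plausible reconstruction of the published network figure (the figure itself is
not machine-readable), organized in the same functional blocks (EMP, ED,
SP-ED, Bifidobacterium shunt, sugar routes, SCFA production, methanogenesis,
sulfate reduction, Wood-Ljungdahl).  The constraint matrix is a SYNTHETIC
stand-in with the published dimensions (155 x 101), generated from this
topology by fibrenmf.network.build_completeness_constraints.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from fibrenmf.network import (  # noqa: E402
    build_completeness_constraints,
    load_reaction_table,
    write_constraint_matrix,
)

DATA = ROOT / "src" / "fibrenmf" / "data"

# id, members, substrate, product, module  (KO-pathway reactions 1..68)
KO_REACTIONS = [
    (1, "K01809", "mannose", "F6P", "mannose"),
    (2, "K00882", "fructose", "FBP", "fructose"),
    (3, "K06859", "glucose", "G6P", "EMP"),
    (4, "K01810", "G6P", "F6P", "EMP"),
    (5, "K01803", "F6P", "FBP", "EMP"),
    (6, "K00150", "FBP", "GAP", "EMP"),
    (7, "K00134", "FBP", "GAP", "EMP"),
    (8, "K00927", "GAP", "PG3", "EMP"),
    (9, "K00131", "KDPG", "PG3", "SPED"),
    (10, "K01834", "PG3", "PEP", "EMP"),
    (11, "K01689", "PEP", "PYR", "EMP"),
    (12, "K00036", "G6P", "PGLCN", "ED"),
    (13, "K01057", "PGLCN", "KDPG", "ED"),
    (14, "K07404", "gluconate", "KDG", "SPED"),
    (15, "K01690", "KDPG", "GAP", "ED"),
    (16, "K00874", "KDG", "KDPG", "SPED"),
    (17, "K00041", "galactose", "GAL1P", "galactose"),
    (18, "K01685", "galacturonate", "KDG", "pectin_fermentation"),
    (19, "K00883", "galactose", "PYR", "galactose_alt"),
    (20, "K00849", "galactose", "GAL1P", "galactose"),
    (21, "K00965", "GAL1P", "G6P", "galactose"),
    (22, "K01818", "fucose", "FUCULOSE", "fucose"),
    (23, "K00879", "FUCULOSE", "FUC1P", "fucose"),
    (24, "K01628", "FUC1P", "LACALD", "fucose"),
    (25, "K01813", "rhamnose", "LACALD", "rhamnose"),
    (26, "K01804", "arabinose", "RIB5P", "arabinose"),
    (27, "K01786", "fructose", "F6P", "fructose"),
    (28, "K03077", "RIB5P", "XYL5P", "arabinose"),
    (29, "K03080", "XYL5P", "GAP", "pentose"),
    (30, "K00854", "xylose", "XYL5P", "xylose"),
    (31, "K01621", "F6P", "ACCOA", "bif_shunt"),
    (32, "K00169;K00170;K00171;K00172", "PYR", "ACCOA", "pyruvate"),
    (33, "K00627", "PYR", "ACCOA", "pyruvate"),
    (34, "K03737", "PYR", "ACETOIN", "butanediol"),
    (35, "K00656", "PYR", "ACCOA", "pyruvate"),
    (36, "K04020", "ACCOA", "acetate", "acetate_alt"),
    (37, "K00625", "ACCOA", "ACAC", "acetone"),
    (38, "K00925", "ACCOA", "acetate", "acetate"),
    (39, "K00626", "ACCOA", "BUCOA", "butyrate"),
    (40, "K01034;K01035", "BUCOA", "butyrate", "butyrate"),
    (41, "K00634", "BUCOA", "butyrate", "butyrate"),
    (42, "K00929", "BUCOA", "butyrate", "butyrate"),
    (43, "K01574", "ACAC", "acetone", "acetone"),
    (44, "K01938;K00288;K01491", "CO2", "METHF", "WL"),
    (45, "K00297", "METHF", "ACCOA", "WL"),
    (46, "K00004;K03366", "ACETOIN", "butanediol", "butanediol"),
    (47, "K00016", "PYR", "lactate", "lactate"),
    (48, "K01847", "lactate", "PROPCOA", "propionate"),
    (49, "K01848;K01849", "lactate", "PROPCOA", "propionate"),
    (50, "K01026", "PROPCOA", "propionate", "propionate"),
    (51, "K00672", "CO2", "FH4MPT", "methanogenesis"),
    (52, "K01499", "FH4MPT", "MYLH4MPT", "methanogenesis"),
    (53, "K00319", "MYLH4MPT", "MENH4MPT", "methanogenesis"),
    (54, "K13942", "MYLH4MPT", "MENH4MPT", "methanogenesis"),
    (55, "K00320", "MENH4MPT", "ME4MPT", "methanogenesis"),
    (56, "K00577;K00578;K00579;K00580;K00581;K00582;K00583;K00584", "ME4MPT", "MECOM", "methanogenesis"),
    (57, "K00399;K00401;K00402", "MECOM", "methane", "methanogenesis"),
    (58, "K01699;K13919;K13920", "LACALD", "PRPD", "propanediol"),
    (59, "K13922", "PRPD", "propionate", "propanediol"),
    (60, "K13788", "ACCOA", "acetate", "acetate_alt"),
    (61, "K15024", "METHF", "ACCOA", "WL"),
    (62, "K00955", "sulfate", "APS", "sulfur"),
    (63, "K00956;K00957", "sulfate", "APS", "sulfur"),
    (64, "K00958", "sulfate", "APS", "sulfur"),
    (65, "K00394;K00395", "APS", "SO3", "sulfur"),
    (66, "K11180;K11181", "SO3", "H2S", "sulfur"),
    (67, "K00380;K00381", "H2S", "SO3", "sulfur"),
    (68, "K00385", "SO3", "H2S", "sulfur"),
]

# family, substrate, product, module  (GH/PL cleavage steps; fibre pool -> sugar)
CAZYMES = [
    ("GH2", "mucin", "galactose", "mucin_cleavage"),
    ("GH3", "xylan", "xylose", "xylan_cleavage"),
    ("GH5", "cellulose", "glucose", "cellulose_cleavage"),
    ("GH8", "xylan", "xylose", "xylan_cleavage"),
    ("GH9", "cellulose", "glucose", "cellulose_cleavage"),
    ("GH10", "xylan", "xylose", "xylan_cleavage"),
    ("GH13", "starch", "glucose", "starch_cleavage"),
    ("GH16", "hemicellulose", "glucose", "hemicellulose_cleavage"),
    ("GH26", "hemicellulose", "mannose", "hemicellulose_cleavage"),
    ("GH28", "pectin", "galacturonate", "pectin_cleavage"),
    ("GH29", "mucin", "fucose", "mucin_cleavage"),
    ("GH30", "xylan", "xylose", "xylan_cleavage"),
    ("GH32", "fructan", "fructose", "fructan_cleavage"),
    ("GH33", "mucin", "sialate", "mucin_cleavage"),
    ("GH35", "pectin", "galactose", "pectin_cleavage"),
    ("GH39", "xylan", "xylose", "xylan_cleavage"),
    ("GH43", "pectin", "arabinose", "pectin_cleavage"),
    ("GH44", "cellulose", "glucose", "cellulose_cleavage"),
    ("GH48", "cellulose", "glucose", "cellulose_cleavage"),
    ("GH51", "xylan", "arabinose", "xylan_cleavage"),
    ("GH74", "hemicellulose", "glucose", "hemicellulose_cleavage"),
    ("GH84", "mucin", "glucose", "mucin_cleavage"),
    ("GH91", "fructan", "fructose", "fructan_cleavage"),
    ("GH94", "cellulose", "glucose", "cellulose_cleavage"),
    ("GH95", "mucin", "fucose", "mucin_cleavage"),
    ("GH101", "glycoprotein", "galactose", "glycoprotein_cleavage"),
    ("GH115", "xylan", "galacturonate", "xylan_cleavage"),
    ("GH120", "xylan", "xylose", "xylan_cleavage"),
    ("GH127", "pectin", "arabinose", "pectin_cleavage"),
    ("GH129", "glycoprotein", "galactose", "glycoprotein_cleavage"),
    ("PL1", "pectin", "galacturonate", "pectin_cleavage"),
    ("PL9", "pectin", "galacturonate", "pectin_cleavage"),
    ("PL11", "pectin", "rhamnose", "pectin_cleavage"),
]

EXTRACELLULAR = [
    "cellulose", "hemicellulose", "xylan", "starch", "pectin", "fructan",
    "mucin", "glycoprotein", "glucose", "fructose", "mannose", "galactose",
    "arabinose", "xylose", "fucose", "rhamnose", "sialate", "galacturonate",
    "gluconate", "lactate", "acetate", "butyrate", "propionate", "butanediol",
    "acetone", "methane", "H2S", "sulfate", "CO2",
]
INTRACELLULAR = [
    "G6P", "F6P", "FBP", "GAP", "PG3", "PEP", "PYR", "PGLCN", "KDPG", "KDG",
    "GAL1P", "FUCULOSE", "FUC1P", "LACALD", "PRPD", "RIB5P", "XYL5P", "ACCOA",
    "ACAC", "BUCOA", "ACETOIN", "METHF", "FH4MPT", "MYLH4MPT", "MENH4MPT",
    "ME4MPT", "MECOM", "APS", "SO3", "PROPCOA",
]

N_CONSTRAINT_ROWS = 155


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "aft_id": f"AFT_{i}", "kind": "KO-pathway", "members": members,
            "substrate": sub, "product": prod, "module": mod,
        }
        for i, members, sub, prod, mod in KO_REACTIONS
    ] + [
        {
            "aft_id": fam, "kind": "PL" if fam.startswith("PL") else "GH",
            "members": fam, "substrate": sub, "product": prod, "module": mod,
        }
        for fam, sub, prod, mod in CAZYMES
    ]
    pd.DataFrame(rows).to_csv(DATA / "reactions.tsv", sep="\t", index=False)
    met = pd.DataFrame(
        [{"metabolite_id": m, "compartment": "extracellular"} for m in EXTRACELLULAR]
        + [{"metabolite_id": m, "compartment": "intracellular"} for m in INTRACELLULAR]
    )
    met.to_csv(DATA / "metabolites.tsv", sep="\t", index=False)

    net = load_reaction_table(DATA / "reactions.tsv", DATA / "metabolites.tsv")
    assert net.n_features == 101, net.n_features
    full = build_completeness_constraints(net)
    print(f"{full.n_constraints} completeness rows available")
    F = build_completeness_constraints(net, n_rows=N_CONSTRAINT_ROWS)
    write_constraint_matrix(F, DATA / "constraints_synthetic.tsv")
    print(f"wrote {F.n_constraints} x {len(F.aft_order)} synthetic constraint matrix")


if __name__ == "__main__":
    main()
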