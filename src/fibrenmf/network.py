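"""The fibre-degradation reaction network and pathway-completeness constraints.

The analysis rests on a curated, simplified metabolic network of anaerobic
fibre and mucin degradation in the gut: fibre pools are cleaved by glycoside
hydrolases (GH) and polysaccharide lyases (PL) into sugars, which are taken up
and fermented through well-characterized pathways (EMP, ED, semi-phosphorylative
ED, the Bifidobacterium shunt, fucose/rhamnose routes, ...) down to short-chain
fatty acids and hydrogenotrophic sinks (methanogenesis, sulfate reduction,
Wood-Ljungdahl acetogenesis).  Every pathway step is an *aggregated functional
trait* (AFT): either one KO (or a small KO aggregation) representative of the
step, or one GH/PL family.  The reference registry shipped with the package
carries 68 KO-pathway AFTs and 33 GH/PL AFTs, 101 features in total.

A profile (a nonnegative vector over AFTs) is biologically meaningful only if
it carries *complete* intracellular pathways: an enzyme consuming an
intracellular metabolite is useless in a community that cannot produce that
metabolite.  This is expressed as linear inequalities F h <= 0, with rows such
as ``h_consumer - sum(h_producers) <= 0``.

Note on provenance: the KO memberships and GH/PL family list of the packaged
registry are the published selection; the metabolite graph topology and the
packaged constraint matrix are a plausible *reconstruction* (the published
topology is only available as a figure), so they are clearly labelled
synthetic where applicable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SchemaError

KINDS = ("KO-pathway", "GH", "PL")


class NetworkError(ValueError):
    """The reaction registry violates a structural invariant."""


@dataclass
class AftEntry:
    """One aggregated functional trait: a pathway step or a CAZyme family."""

    aft_id: str
    kind: str
    members: list[str]
    substrate_node: str
    product_node: str
    module_label: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise NetworkError(f"{self.aft_id}: unknown kind {self.kind!r}")
        if not self.members:
            raise NetworkError(f"{self.aft_id}: empty member list")


@dataclass
class MetabolicNetwork:
    """Metabolite graph plus the ordered AFT list defining the feature space."""

    metabolites: dict[str, str]  # id -> "intracellular" | "extracellular"
    afts: list[AftEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        member_owner: dict[str, str] = {}
        for a in self.afts:
            if a.aft_id in seen:
                raise NetworkError(f"duplicate aft_id {a.aft_id!r}")
            seen.add(a.aft_id)
            for m in a.members:
                if m in member_owner:
                    raise NetworkError(
                        f"specificity violation: member {m!r} appears in both "
                        f"{member_owner[m]!r} and {a.aft_id!r}"
                    )
                member_owner[m] = a.aft_id
            for node in (a.substrate_node, a.product_node):
                if node not in self.metabolites:
                    raise NetworkError(f"{a.aft_id}: unknown metabolite {node!r}")
        for mid, comp in self.metabolites.items():
            if comp not in ("intracellular", "extracellular"):
                raise NetworkError(f"metabolite {mid!r}: bad compartment {comp!r}")

    @property
    def n_features(self) -> int:
        return len(self.afts)

    @property
    def aft_ids(self) -> list[str]:
        return [a.aft_id for a in self.afts]

    @property
    def feature_index(self) -> dict[str, int]:
        return {a.aft_id: i for i, a in enumerate(self.afts)}

    def producers(self, metabolite: str) -> list[str]:
        return [a.aft_id for a in self.afts if a.product_node == metabolite]

    def consumers(self, metabolite: str) -> list[str]:
        return [a.aft_id for a in self.afts if a.substrate_node == metabolite]

    def kind_mask(self, *kinds: str) -> np.ndarray:
        return np.array([a.kind in kinds for a in self.afts])


@dataclass
class ConstraintMatrix:
    """Linear pathway-completeness constraints F, semantics F h^T <= 0."""

    values: np.ndarray  # constraints x features
    aft_order: list[str]
    row_ids: list[str] = field(default_factory=list)
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.aft_order):
            raise NetworkError(
                f"constraint matrix shape {self.values.shape} does not match "
                f"{len(self.aft_order)} features"
            )
        if not self.row_ids:
            self.row_ids = [f"c{i}" for i in range(self.values.shape[0])]
        for i, row in enumerate(self.values):
            if self.values.shape[0] and not (np.any(row > 0) and np.any(row < 0)):
                raise NetworkError(
                    f"degenerate constraint row {self.row_ids[i]!r}: rows must mix "
                    "positive and negative coefficients"
                )

    @property
    def n_constraints(self) -> int:
        return self.values.shape[0]

    def restrict(self, feature_ids: list[str], keep_partial: bool = False) -> "ConstraintMatrix | None":
        """Restrict columns to ``feature_ids``.

        Rows whose support is not fully retained are dropped unless
        ``keep_partial``; returns None if no valid row remains.
        """
        pos = {f: i for i, f in enumerate(self.aft_order)}
        cols = [pos[f] for f in feature_ids]
        sub = self.values[:, cols]
        if keep_partial:
            keep = [i for i, r in enumerate(sub) if np.any(r > 0) and np.any(r < 0)]
        else:
            retained = np.zeros(len(self.aft_order), dtype=bool)
            retained[cols] = True
            keep = [
                i
                for i in range(self.n_constraints)
                if np.all(retained[np.nonzero(self.values[i])[0]])
            ]
        if not keep:
            return None
        return ConstraintMatrix(
            sub[keep], list(feature_ids), [self.row_ids[i] for i in keep], self.tolerance
        )


# ---------------------------------------------------------------------------
# loading


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise SchemaError(f"{path}: empty table")
    return df


def load_reaction_table(path, metabolite_path) -> MetabolicNetwork:
    """Read the reaction registry and metabolite table (TSV dialect).

    Registry columns: aft_id, kind, members (';'-separated), substrate,
    product, module.  Metabolite columns: metabolite_id, compartment.
    Feature order is the file order.
    """
    reg = _read_tsv(path)
    met = _read_tsv(metabolite_path)
    for col in ("aft_id", "kind", "members", "substrate", "product", "module"):
        if col not in reg.columns:
            raise SchemaError(f"registry missing column {col!r}")
    for col in ("metabolite_id", "compartment"):
        if col not in met.columns:
            raise SchemaError(f"metabolite table missing column {col!r}")
    metabolites = dict(zip(met["metabolite_id"], met["compartment"]))
    afts = [
        AftEntry(
            aft_id=r.aft_id,
            kind=r.kind,
            members=[m for m in str(r.members).split(";") if m],
            substrate_node=r.substrate,
            product_node=r.product,
            module_label=r.module,
        )
        for r in reg.itertuples()
    ]
    return MetabolicNetwork(metabolites=metabolites, afts=afts)


def load_constraint_matrix(path, network: MetabolicNetwork) -> ConstraintMatrix:
    """Read a constraint matrix TSV (first column row id, then aft_id columns).

    Columns may appear in any order; they are reindexed to the network's
    feature order.  Every column label must be a known AFT and every row must
    mix signs (a one-signed row is degenerate).
    """
    df = _read_tsv(path)
    row_ids = df.iloc[:, 0].tolist()
    df = df.iloc[:, 1:]
    known = set(network.aft_ids)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"constraint columns not in network: {unknown[:5]}")
    missing = [c for c in network.aft_ids if c not in set(df.columns)]
    if missing:
        raise SchemaError(f"constraint matrix missing columns: {missing[:5]}")
    vals = df[network.aft_ids].to_numpy(dtype=float)
    for i, row in enumerate(vals):
        if not np.any(row):
            raise SchemaError(f"all-zero constraint row {row_ids[i]!r}")
    return ConstraintMatrix(vals, list(network.aft_ids), [str(r) for r in row_ids])


def write_constraint_matrix(F: ConstraintMatrix, path) -> None:
    df = pd.DataFrame(F.values, columns=F.aft_order)
    df.insert(0, "constraint_id", F.row_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# constraint generation


def build_chain_constraints(network: MetabolicNetwork) -> ConstraintMatrix:
    """Generate producer/consumer chain constraints for a network.

    For each intracellular metabolite m and each AFT b consuming m, emit one
    row with +1 at b and -1 at every AFT producing m, i.e. enforce
    ``h_b <= sum_a h_a`` over producers a: a profile may carry a consumer of
    an intracellular metabolite only to the extent it carries producers.

    This generator serves synthetic networks; it is a reconstruction of the
    published pathway-completeness semantics, not the published matrix.
    """
    idx = network.feature_index
    rows, ids = [], []
    for mid, comp in network.metabolites.items():
        if comp != "intracellular":
            continue
        cons = network.consumers(mid)
        prod = network.producers(mid)
        if cons and not prod:
            raise NetworkError(f"intracellular metabolite {mid!r} is consumed but never produced")
        for b in cons:
            row = np.zeros(network.n_features)
            row[idx[b]] = 1.0
            for a in prod:
                row[idx[a]] = -1.0
            rows.append(row)
            ids.append(f"chain:{mid}:{b}")
    vals = np.array(rows) if rows else np.zeros((0, network.n_features))
    return ConstraintMatrix(vals, list(network.aft_ids), ids)


def build_completeness_constraints(
    network: MetabolicNetwork, n_rows: int | None = None
) -> ConstraintMatrix:
    """Richer synthetic pathway-completeness family (for the packaged fixture).

    Emits, in canonical order: (1) the chain rows of
    :func:`build_chain_constraints`; (2) downstream rows (+1 at a producer of
    an intracellular metabolite, -1 at its consumers: do not produce what the
    profile cannot consume); (3) uptake rows over *extracellular* exchanged
    metabolites that have both producers and consumers (e.g. a profile
    fermenting glucose should carry glycosidases releasing it); (4) their
    downstream counterparts; (5) module closure rows (last step of a module
    <= first step).  Optionally truncated to ``n_rows``.
    """
    idx = network.feature_index
    p = network.n_features
    rows: list[np.ndarray] = []
    ids: list[str] = []

    def add(pos: str, negs: list[str], tag: str) -> None:
        if not negs:
            return
        row = np.zeros(p)
        row[idx[pos]] = 1.0
        for a in negs:
            row[idx[a]] = -1.0
        if row[idx[pos]] > 0:  # pos may coincide with a neg in cycles; keep only mixed rows
            if np.any(row < 0):
                rows.append(row)
                ids.append(tag)

    chain = build_chain_constraints(network)
    rows.extend(chain.values)
    ids.extend(chain.row_ids)
    intracellular = [m for m, c in network.metabolites.items() if c == "intracellular"]
    for mid in intracellular:
        cons, prod = network.consumers(mid), network.producers(mid)
        for a in prod:
            add(a, [b for b in cons if b != a], f"down:{mid}:{a}")
    exchanged = [
        m
        for m, c in network.metabolites.items()
        if c == "extracellular" and network.producers(m) and network.consumers(m)
    ]
    for mid in exchanged:
        cons, prod = network.consumers(mid), network.producers(mid)
        for b in cons:
            add(b, [a for a in prod if a != b], f"uptake:{mid}:{b}")
        for a in prod:
            add(a, [b for b in cons if b != a], f"downext:{mid}:{a}")
    modules: dict[str, list[str]] = {}
    for a in network.afts:
        modules.setdefault(a.module_label, []).append(a.aft_id)
    for mod, members in modules.items():
        if len(members) >= 2 and members[0] != members[-1]:
            add(members[-1], [members[0]], f"closure:{mod}")
    vals = np.array(rows)
    if n_rows is not None:
        if len(rows) < n_rows:
            raise NetworkError(
                f"only {len(rows)} completeness rows available, {n_rows} requested"
            )
        vals, ids = vals[:n_rows], ids[:n_rows]
    return ConstraintMatrix(vals, list(network.aft_ids), ids)


# ---------------------------------------------------------------------------
# feasibility


@dataclass
class FeasibilityReport:
    max_violation: np.ndarray  # per profile
    feasible: np.ndarray  # per profile
    tol: float

    @property
    def all_feasible(self) -> bool:
        return bool(self.feasible.all())


def check_feasibility(H: np.ndarray, F: ConstraintMatrix, tol: float = 1e-8) -> FeasibilityReport:
    """Per-profile maximum of F h^T; feasible iff <= tol."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[1] != F.values.shape[1]:
        raise ValueError(
            f"profile matrix has {H.shape[1]} features, constraints have {F.values.shape[1]}"
        )
    if F.n_constraints == 0:
        mv = np.zeros(H.shape[0])
    else:
        mv = (F.values @ H.T).max(axis=0)
    return FeasibilityReport(max_violation=mv, feasible=mv <= tol, tol=tol)


# ---------------------------------------------------------------------------
# packaged reference fixture


def _data_path(name: str):
    return resources.files("fibrenmf.data").joinpath(name)


def reference_network() -> MetabolicNetwork:
    """The packaged 101-AFT registry (68 KO-pathway + 33 GH/PL entries).

    KO memberships and family names follow the published selection; the
    metabolite topology is a reconstruction of the published network figure.
    """
    with resources.as_file(_data_path("reactions.tsv")) as reg, resources.as_file(
        _data_path("metabolites.tsv")
    ) as met:
        return load_reaction_table(reg, met)


def reference_constraints(network: MetabolicNetwork | None = None) -> ConstraintMatrix:
    """The packaged synthetic 155 x 101 pathway-completeness matrix.

    A synthetic stand-in generated from the reconstructed topology by
    :func:`build_completeness_constraints` (see scripts/make_fixtures.py),
    matching the published dimensions.
    """
    network = network or reference_network()
    with resources.as_file(_data_path("constraints_synthetic.tsv")) as f:
        return load_constraint_matrix(f, network)
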