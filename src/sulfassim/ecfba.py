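"""Enzyme-constrained flux balance analysis with a compact sulfur network.

Flux balance analysis maximises flux through a biomass reaction subject to
steady state (S v = 0) and flux bounds. The enzyme constraint treats enzymes
as capacity that catalysed fluxes consume: each unidirectional flux v_i on an
enzyme with turnover kcat_i uses v_i / kcat_i of that enzyme, and total
weighted usage is capped by a shared pool P. Reversible reactions are split
into forward/reverse non-negative fluxes, each drawing capacity.

The built-in model is a compact sulfur-assimilation network: sulfate is
reduced to sulfide through the Met3 -> Met14 -> Met16 -> Met5/Met10 chain,
Met2 acetylates homoserine to O-acetylhomoserine (OAH), and a homocysteine
synthase (Met15, or the far less efficient Yll058w) condenses OAH with
sulfide into homocysteine (+ acetate + hydrogen); Met6 and Cys4/Cys3 convert
homocysteine to methionine and cysteine, which the biomass reaction consumes.
"""

from __future__ import annotations

import copy as _copy
import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

FORMAT_TAG = "sulfassim-model-v1"
FEAS_TOL = 1e-9
ZERO_TOL = 1e-7
_INF = 1e6


@dataclasses.dataclass
class Metabolite:
    id: str
    compartment: str = "c"
    s_atoms: float = 0.0  # tracked element (sulfur) count


@dataclasses.dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = _INF
    enzyme: str | None = None
    gene: str | None = None
    exchange: bool = False  # exempt from enzyme constraint and S balance


@dataclasses.dataclass
class Enzyme:
    id: str
    kcat: float  # 1/h per unit enzyme
    weight: float = 1.0

    def __post_init__(self):
        if self.kcat <= 0:
            raise ValueError(f"kcat must be > 0 for enzyme {self.id}")


@dataclasses.dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    fluxes: dict[str, float]
    biomass_flux: float
    enzyme_usage: dict[str, float]
    binding_constraints: list[str]
    pool_shadow_price: float | None = None

    def __repr__(self):
        return f"<FluxResult {self.status}, biomass={self.biomass_flux:.6g}>"


class MetabolicModel:
    """Stoichiometry + enzyme kcat/pool constraints + objective."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        enzymes: Sequence[Enzyme] = (),
        enzyme_pool: float = math.inf,
        objective: str = "BIOMASS",
        enzyme_constrained: bool = False,
    ):
        self.metabolites = {m.id: m for m in metabolites}
        self.reactions = {r.id: r for r in reactions}
        self.enzymes = {e.id: e for e in enzymes}
        self.enzyme_pool = enzyme_pool
        self.objective = objective
        self.enzyme_constrained = enzyme_constrained
        self._validate()

    def _validate(self):
        for r in self.reactions.values():
            if r.lower_bound > r.upper_bound:
                raise ValueError(f"bounds inverted on {r.id}")
            for m in r.stoichiometry:
                if m not in self.metabolites:
                    raise ValueError(f"reaction {r.id} uses unknown metabolite {m}")
            if r.enzyme is not None and r.enzyme not in self.enzymes:
                raise ValueError(f"reaction {r.id} references unknown enzyme {r.enzyme}")

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- element bookkeeping -------------------------------------------------
    def sulfur_imbalance(self, reaction_id: str) -> float:
        r = self.reactions[reaction_id]
        return sum(coef * self.metabolites[m].s_atoms for m, coef in r.stoichiometry.items())

    def check_sulfur_balance(self, tol: float = 1e-12) -> bool:
        """True when every non-exchange reaction conserves sulfur atoms."""
        return all(
            abs(self.sulfur_imbalance(rid)) <= tol
            for rid, r in self.reactions.items()
            if not r.exchange
        )

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": FORMAT_TAG,
            "metabolites": [dataclasses.asdict(m) for m in self.metabolites.values()],
            "reactions": [dataclasses.asdict(r) for r in self.reactions.values()],
            "enzymes": [dataclasses.asdict(e) for e in self.enzymes.values()],
            "enzyme_pool": self.enzyme_pool if math.isfinite(self.enzyme_pool) else None,
            "objective": self.objective,
            "enzyme_constrained": self.enzyme_constrained,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MetabolicModel":
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"model file not found: {p}")
        doc = json.loads(p.read_text())
        if doc.get("format") != FORMAT_TAG:
            raise ValueError(
                f"unsupported model dialect {doc.get('format')!r}; "
                f"expected a JSON document with format: {FORMAT_TAG}"
            )
        pool = doc.get("enzyme_pool")
        return cls(
            [Metabolite(**m) for m in doc["metabolites"]],
            [Reaction(**r) for r in doc["reactions"]],
            [Enzyme(**e) for e in doc["enzymes"]],
            enzyme_pool=math.inf if pool is None else pool,
            objective=doc["objective"],
            enzyme_constrained=doc.get("enzyme_constrained", False),
        )

    def optimize(self) -> FluxResult:
        return solve_fba(self)


def load_external_model(path: str | Path) -> MetabolicModel:
    """Optional adapter: load a model from the package's JSON exchange format.

    Raises a clean error naming the expected format for anything else.
    """
    return MetabolicModel.from_json(path)


# ---------------------------------------------------------------------------
# Built-in compact sulfur network

DEFAULT_KCATS = {
    "Met3": 100.0,
    "Met14": 100.0,
    "Met16": 100.0,
    "Met5_Met10": 100.0,
    "Met2": 100.0,
    "Met15": 100.0,
    "Yll058w": 1.0,  # ~100x less efficient than Met15
    "Met6": 100.0,
    "Cys4": 100.0,
    "Cys3": 100.0,
}


def build_sulfur_model(
    medium: str = "sulfate",
    kcats: Mapping[str, float] | None = None,
    enzyme_pool: float = 1.0,
    sulfate_uptake: float = 1.0,
    organosulfur_uptake: float = 1.0,
) -> MetabolicModel:
    """Construct the compact sulfur-assimilation network.

    ``medium`` is one of ``sulfate`` (inorganic sulfate only), ``met``
    (methionine + cysteine uptake, no sulfate) or ``both``. Every enzymatic
    step carries an enzyme with a kcat; exchanges and the biomass sink are
    uncatalysed. Sulfur atoms balance across every non-exchange reaction.
    """
    if medium not in ("sulfate", "met", "both"):
        raise ValueError(f"unknown medium {medium!r}")
    kc = dict(DEFAULT_KCATS)
    if kcats:
        kc.update(kcats)

    s1 = dict(s_atoms=1.0)
    mets = [
        Metabolite("so4", **s1),
        Metabolite("aps", **s1),
        Metabolite("paps", **s1),
        Metabolite("so3", **s1),
        Metabolite("h2s", **s1),
        Metabolite("hse"),  # homoserine
        Metabolite("oah"),  # O-acetylhomoserine
        Metabolite("hcys", **s1),
        Metabolite("cyst", **s1),  # cystathionine
        Metabolite("met", **s1),
        Metabolite("cys", **s1),
        Metabolite("ac"),
        Metabolite("h"),
        Metabolite("biomass", s_atoms=1.0),  # 0.6 Met + 0.4 Cys worth of S
    ]

    so4_on = medium in ("sulfate", "both")
    org_on = medium in ("met", "both")
    hcys_stoich = {"oah": -1.0, "h2s": -1.0, "hcys": 1.0, "ac": 1.0, "h": 1.0}
    rxns = [
        Reaction("EX_so4", {"so4": 1.0}, upper_bound=sulfate_uptake if so4_on else 0.0,
                 exchange=True),
        Reaction("MET3", {"so4": -1.0, "aps": 1.0}, enzyme="Met3", gene="MET3"),
        Reaction("MET14", {"aps": -1.0, "paps": 1.0}, enzyme="Met14", gene="MET14"),
        Reaction("MET16", {"paps": -1.0, "so3": 1.0}, enzyme="Met16", gene="MET16"),
        Reaction("MET5_MET10", {"so3": -1.0, "h2s": 1.0}, enzyme="Met5_Met10",
                 gene="MET5_MET10"),
        Reaction("HSE_SUPPLY", {"hse": 1.0}, upper_bound=_INF, exchange=True),
        Reaction("MET2", {"hse": -1.0, "oah": 1.0}, enzyme="Met2", gene="MET2"),
        Reaction("MET15", dict(hcys_stoich), enzyme="Met15", gene="MET15"),
        Reaction("YLL058W", dict(hcys_stoich), reversible=True,
                 lower_bound=-_INF, enzyme="Yll058w", gene="YLL058W"),
        Reaction("MET6", {"hcys": -1.0, "met": 1.0}, enzyme="Met6", gene="MET6"),
        Reaction("CYS4", {"hcys": -1.0, "cyst": 1.0}, enzyme="Cys4", gene="CYS4"),
        Reaction("CYS3", {"cyst": -1.0, "cys": 1.0}, enzyme="Cys3", gene="CYS3"),
        Reaction("EX_h2s", {"h2s": -1.0}, exchange=True),
        Reaction("EX_ac", {"ac": -1.0}, exchange=True),
        Reaction("EX_h", {"h": -1.0}, exchange=True),
        Reaction("EX_met", {"met": 1.0},
                 upper_bound=organosulfur_uptake if org_on else 0.0, exchange=True),
        Reaction("EX_cys", {"cys": 1.0},
                 upper_bound=organosulfur_uptake if org_on else 0.0, exchange=True),
        Reaction("BIOMASS", {"met": -0.6, "cys": -0.4, "biomass": 1.0}),
        Reaction("EX_biomass", {"biomass": -1.0}, exchange=True),
    ]
    enzymes = [Enzyme(name, kcat) for name, kcat in kc.items()]
    model = MetabolicModel(mets, rxns, enzymes, enzyme_pool=enzyme_pool,
                           objective="BIOMASS")
    return add_enzyme_constraints(model)


def add_enzyme_constraints(model: MetabolicModel) -> MetabolicModel:
    """Enable the shared enzyme pool: each catalysed unidirectional flux v_i
    consumes v_i / kcat_i of its enzyme; total weighted usage <= pool.

    Pure transformation; exchanges and other uncatalysed reactions are exempt.
    """
    for r in model.reactions.values():
        if r.enzyme is not None and model.enzymes[r.enzyme].kcat <= 0:
            raise ValueError(f"kcat must be > 0 for enzyme {r.enzyme}")
    out = model.copy()
    out.enzyme_constrained = True
    return out


def _split_variables(model: MetabolicModel):
    """One LP variable per unidirectional flux; reversibles get fwd + rev."""
    variables = []  # (reaction id, direction +1/-1, lb, ub)
    for r in model.reactions.values():
        ub_f = max(r.upper_bound, 0.0)
        variables.append((r.id, +1, max(r.lower_bound, 0.0), ub_f))
        if r.reversible or r.lower_bound < 0:
            ub_r = max(-r.lower_bound, 0.0)
            variables.append((r.id, -1, 0.0, ub_r))
    return variables


def solve_fba(model: MetabolicModel) -> FluxResult:
    """Maximise the objective flux subject to steady state, bounds, and
    (when enabled) the enzyme pool. Infeasibility is a status, not an error."""
    variables = _split_variables(model)
    met_ids = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    n = len(variables)

    A_eq = np.zeros((len(met_ids), n))
    c = np.zeros(n)
    bounds = []
    pool_row = np.zeros(n)
    for j, (rid, sign, lb, ub) in enumerate(variables):
        r = model.reactions[rid]
        for m, coef in r.stoichiometry.items():
            A_eq[met_index[m], j] = sign * coef
        if rid == model.objective and sign == +1:
            c[j] = -1.0  # linprog minimises
        if model.enzyme_constrained and r.enzyme is not None:
            e = model.enzymes[r.enzyme]
            pool_row[j] = e.weight / e.kcat
        bounds.append((lb, min(ub, _INF)))

    A_ub = b_ub = None
    if model.enzyme_constrained and math.isfinite(model.enzyme_pool):
        A_ub = pool_row.reshape(1, -1)
        b_ub = np.array([model.enzyme_pool])

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(len(met_ids)),
                  bounds=bounds, method="highs")

    if res.status == 2:
        return FluxResult("infeasible", {}, 0.0, {}, [])
    if res.status == 3:
        return FluxResult("unbounded", {}, math.inf, {}, [])
    if not res.success:
        return FluxResult("infeasible", {}, 0.0, {}, [])

    net = {rid: 0.0 for rid in model.reactions}
    usage = {eid: 0.0 for eid in model.enzymes}
    for j, (rid, sign, _, _) in enumerate(variables):
        v = float(res.x[j])
        net[rid] += sign * v
        enz = model.reactions[rid].enzyme
        if enz is not None:
            usage[enz] += v / model.enzymes[enz].kcat

    binding = []
    shadow = None
    if A_ub is not None:
        slack = model.enzyme_pool - float(pool_row @ res.x)
        if slack <= ZERO_TOL:
            binding.append("enzyme_pool")
        shadow = float(-res.ineqlin.marginals[0]) if res.ineqlin is not None else None
    for j, (rid, sign, lb, ub) in enumerate(variables):
        if ub < _INF and res.x[j] >= ub - ZERO_TOL and ub > 0:
            binding.append(f"{rid}:{'fwd' if sign > 0 else 'rev'}_ub")

    biomass = max(net.get(model.objective, 0.0), 0.0)
    if biomass < ZERO_TOL:
        biomass = 0.0
    return FluxResult("optimal", net, biomass, usage, binding, shadow)


def knockout(model: MetabolicModel, target: str) -> MetabolicModel:
    """Remove every reaction associated with a gene, enzyme or reaction id.

    Pure transformation; the input model is untouched.
    """
    genes = {r.gene for r in model.reactions.values() if r.gene}
    enzymes = set(model.enzymes)
    rxns = set(model.reactions)
    if target not in genes | enzymes | rxns:
        raise KeyError(
            f"unknown id {target!r}; known genes {sorted(genes)}, "
            f"enzymes {sorted(enzymes)}, reactions {sorted(rxns)}"
        )
    out = model.copy()
    doomed = [
        rid
        for rid, r in out.reactions.items()
        if rid == target or r.gene == target or r.enzyme == target
    ]
    for rid in doomed:
        del out.reactions[rid]
    return out


def kcat_scan(
    model: MetabolicModel,
    enzyme_id: str,
    factors: Sequence[float],
    kcat_ref: float | None = None,
) -> pd.DataFrame:
    """Re-solve with kcat(enzyme) = kcat_ref / factor for each factor.

    ``kcat_ref`` defaults to Met15's kcat when present (the efficiency the
    scanned enzyme is measured against), else the enzyme's own kcat. Returns
    a (factor, kcat, biomass, status) table; per-row solve errors are
    recorded, not raised.
    """
    if enzyme_id not in model.enzymes:
        raise KeyError(f"unknown enzyme {enzyme_id!r}")
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be > 0")
    if kcat_ref is None:
        kcat_ref = model.enzymes.get("Met15", model.enzymes[enzyme_id]).kcat
    rows = []
    for f in factors:
        m = model.copy()
        m.enzymes[enzyme_id].kcat = kcat_ref / f
        try:
            res = solve_fba(m)
            rows.append((f, kcat_ref / f, res.biomass_flux, res.status))
        except Exception as exc:  # keep scanning
            rows.append((f, kcat_ref / f, math.nan, f"error: {exc}"))
    return pd.DataFrame(rows, columns=["factor", "kcat", "biomass", "status"])
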