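"""Cell types, daily rates and mutation transitions of the branching-process model.

The tumor is modelled as a multi-type branching process observed once per
day.  A cell's type (its subclone) records two things:

* which — if any — of nine sensitizing driver genes is mutated (*KRAS*,
  *EGFR*, *ALK*, *MET*, *BRAF*, *RET*, *ROS1*, *NTRK*, *HER2*).  Sensitizing
  mutations are mutually exclusive: once one of the nine genes is mutated in
  a lineage, the other eight are blocked (an XOR gate, mirroring the
  clinical mutual exclusivity of e.g. EGFR and KRAS drivers);
* how many resistance mechanisms it carries against each drug class — the
  nine matched inhibitors plus platinum-based chemotherapy.  Counts are
  unbounded: resistance has levels, not a binary switch.

Each day a cell divides with probability ``b = (1 + s) / 2`` (``s`` is the
selection advantage) and dies otherwise.  A division is *asynchronous* —
one daughter keeps the parental type, the other carries exactly one new
mutation — with probability ``u``, the summed probability of all mutation
transitions available to that cell type, and *synchronous* (two identical
daughters) otherwise.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping


class Gene(enum.Enum):
    """The nine sensitizing driver genes, plus ``NONE`` (no driver yet).

    The declaration order is the canonical ordering used for signature
    bit-strings and all per-gene outputs.
    """

    KRAS = "kras"
    EGFR = "egfr"
    ALK = "alk"
    MET = "met"
    BRAF = "braf"
    RET = "ret"
    ROS1 = "ros1"
    NTRK = "ntrk"
    HER2 = "her2"
    NONE = "none"


#: Canonical ordering of the nine sensitizing genes (excludes ``Gene.NONE``).
SENSITIZING_GENES: tuple[Gene, ...] = tuple(g for g in Gene if g is not Gene.NONE)


class DrugClass(enum.Enum):
    """Resistance targets: nine gene-matched inhibitor classes plus platinum."""

    KRASI = "kras_i"
    EGFRI = "egfr_i"
    ALKI = "alk_i"
    METI = "met_i"
    BRAFI = "braf_i"
    RETI = "ret_i"
    ROS1I = "ros1_i"
    NTRKI = "ntrk_i"
    HER2I = "her2_i"
    PT = "pt"


#: One-to-one map from sensitizing gene to its matched inhibitor class.
INHIBITOR_FOR: dict[Gene, DrugClass] = {
    Gene.KRAS: DrugClass.KRASI,
    Gene.EGFR: DrugClass.EGFRI,
    Gene.ALK: DrugClass.ALKI,
    Gene.MET: DrugClass.METI,
    Gene.BRAF: DrugClass.BRAFI,
    Gene.RET: DrugClass.RETI,
    Gene.ROS1: DrugClass.ROS1I,
    Gene.NTRK: DrugClass.NTRKI,
    Gene.HER2: DrugClass.HER2I,
}

_DRUG_ORDER = {d: i for i, d in enumerate(DrugClass)}


@dataclass(frozen=True)
class CellState:
    """A subclone identity: sensitizing gene plus resistance-mechanism counts.

    ``resistance`` is stored as a canonically sorted tuple of
    ``(DrugClass, count)`` pairs with zero counts dropped, so structurally
    equal states hash identically and can key sparse population maps.
    Construct via keyword arguments or :meth:`make`; any mapping passed as
    ``resistance`` is canonicalized.
    """

    gene: Gene = Gene.NONE
    resistance: tuple[tuple[DrugClass, int], ...] = ()

    def __post_init__(self) -> None:
        res = self.resistance
        if isinstance(res, Mapping):
            items: Iterable[tuple[DrugClass, int]] = res.items()
        else:
            items = res
        clean = []
        for drug, count in items:
            if not isinstance(drug, DrugClass):
                raise TypeError(f"resistance key must be DrugClass, got {drug!r}")
            count = int(count)
            if count < 0:
                raise ValueError(f"negative resistance count for {drug}: {count}")
            if count > 0:
                clean.append((drug, count))
        clean.sort(key=lambda dc: _DRUG_ORDER[dc[0]])
        object.__setattr__(self, "resistance", tuple(clean))

    @classmethod
    def make(
        cls,
        gene: Gene = Gene.NONE,
        resistance: Mapping[DrugClass, int] | None = None,
    ) -> "CellState":
        return cls(gene=gene, resistance=resistance or ())

    def resistance_count(self, drug: DrugClass) -> int:
        for d, c in self.resistance:
            if d is drug:
                return c
        return 0

    @property
    def total_resistance(self) -> int:
        return sum(c for _, c in self.resistance)

    @property
    def is_resistant(self) -> bool:
        """True iff the cell carries at least one resistance mechanism."""
        return self.total_resistance >= 1

    def with_sensitization(self, gene: Gene) -> "CellState":
        """The state after gaining a sensitizing mutation (XOR gate enforced)."""
        if gene is Gene.NONE:
            raise ValueError("cannot sensitize to Gene.NONE")
        if self.gene is not Gene.NONE:
            raise ValueError(
                f"cell already sensitized to {self.gene.name}; further "
                "sensitizing mutations are blocked"
            )
        return replace(self, gene=gene)

    def with_extra_resistance(self, drug: DrugClass) -> "CellState":
        """The state after gaining one more resistance mechanism to ``drug``."""
        counts = dict(self.resistance)
        counts[drug] = counts.get(drug, 0) + 1
        return CellState(gene=self.gene, resistance=counts)

    def __repr__(self) -> str:  # compact, e.g. CellState(EGFR, {PT:1})
        res = ", ".join(f"{d.name}:{c}" for d, c in self.resistance)
        return f"CellState({self.gene.name}, {{{res}}})"


def is_resistant(state: CellState) -> bool:
    """Whether a cell of ``state`` counts as drug-resistant (≥1 mechanism)."""
    return state.is_resistant


@dataclass(frozen=True)
class Transition:
    """One available mutation: the target subclone and its per-division probability."""

    target: CellState
    prob: float


# Table of default sensitization probabilities per cell division (calibrated
# values) and the common point-mutation probability used for every
# resistance class.
_DEFAULT_MU_SENS: dict[Gene, float] = {
    Gene.KRAS: 3.15e-5,
    Gene.EGFR: 2.43e-5,
    Gene.ALK: 1.08e-5,
    Gene.MET: 1.35e-5,
    Gene.BRAF: 1.80e-5,
    Gene.RET: 1.35e-5,
    Gene.ROS1: 1.80e-5,
    Gene.NTRK: 1.89e-5,
    Gene.HER2: 0.90e-5,
}
_DEFAULT_MU_RES = 1e-8


@dataclass(frozen=True)
class ModelParams:
    """All model rates and conversion constants.

    Parameters
    ----------
    s
        Selection advantage: the net daily growth bias, so the expected
        population multiplication per day is ``1 + s``.  Default 0.05
        (a fast-growing tumor).
    mu_sens
        Per-division probability of a sensitizing mutation, per gene.
    mu_res
        Per-division probability of gaining one resistance mechanism, per
        drug class.  Default 1e-8 each (single point mutation).
    signature_threshold
        Minimum sensitized-cell fraction for a gene to count as mutated in
        a patient's signature (default 0.05).
    cells_per_cm3
        Packing density used to convert tumor volume to cell count
        (default 1e9 cells per cm³).
    days_per_month
        Calendar conversion used when reporting times in months.
    """

    s: float = 0.05
    mu_sens: Mapping[Gene, float] = field(
        default_factory=lambda: dict(_DEFAULT_MU_SENS)
    )
    mu_res: Mapping[DrugClass, float] = field(
        default_factory=lambda: {d: _DEFAULT_MU_RES for d in DrugClass}
    )
    signature_threshold: float = 0.05
    cells_per_cm3: float = 1e9
    days_per_month: float = 30.44

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def default(cls) -> "ModelParams":
        return cls()

    def validate(self) -> None:
        if not 0.0 <= self.s < 1.0:
            raise ValueError(f"selection advantage s must be in [0, 1), got {self.s}")
        for g in SENSITIZING_GENES:
            mu = self.mu_sens.get(g, 0.0)
            if not 0.0 <= mu <= 1.0:
                raise ValueError(f"mu_sens[{g.name}]={mu} outside [0, 1]")
        for d in DrugClass:
            mu = self.mu_res.get(d, 0.0)
            if not 0.0 <= mu <= 1.0:
                raise ValueError(f"mu_res[{d.name}]={mu} outside [0, 1]")
        if not 0.0 <= self.signature_threshold <= 1.0:
            raise ValueError("signature_threshold must be in [0, 1]")
        if self.cells_per_cm3 <= 0:
            raise ValueError("cells_per_cm3 must be positive")
        if self.days_per_month <= 0:
            raise ValueError("days_per_month must be positive")

    # -- serialization: flat JSON with one key per rate -------------------
    def to_dict(self) -> dict:
        out: dict[str, float] = {"s": self.s}
        for g in SENSITIZING_GENES:
            out[f"mu_{g.value}"] = self.mu_sens.get(g, 0.0)
        for d in DrugClass:
            out[f"mu_res_{d.value.removesuffix('_i')}"] = self.mu_res.get(d, 0.0)
        out["signature_threshold"] = self.signature_threshold
        out["cells_per_cm3"] = self.cells_per_cm3
        out["days_per_month"] = self.days_per_month
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParams":
        mu_sens = {
            g: float(data.get(f"mu_{g.value}", 0.0)) for g in SENSITIZING_GENES
        }
        mu_res = {
            d: float(data.get(f"mu_res_{d.value.removesuffix('_i')}", 0.0))
            for d in DrugClass
        }
        return cls(
            s=float(data.get("s", 0.05)),
            mu_sens=mu_sens,
            mu_res=mu_res,
            signature_threshold=float(data.get("signature_threshold", 0.05)),
            cells_per_cm3=float(data.get("cells_per_cm3", 1e9)),
            days_per_month=float(data.get("days_per_month", 30.44)),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Daily rate arithmetic
# ---------------------------------------------------------------------------


def division_probability(s: float) -> float:
    """Per-day division probability ``b = (1 + s) / 2``.

    At ``s = 0`` the process is critical (division and death equally
    likely); a selection advantage ``s`` lifts ``b`` above one half by
    ``s / 2``.
    """
    if not 0.0 <= s < 1.0:
        raise ValueError(f"selection advantage s must be in [0, 1), got {s}")
    return 0.5 * (1.0 + s)


def death_probability(b: float) -> float:
    """Per-day death probability ``d = 1 - b``."""
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"division probability b must be in [0, 1], got {b}")
    return 1.0 - b


def split_division(b: float, u: float) -> tuple[float, float]:
    """Split ``b`` into synchronous and asynchronous division probabilities.

    ``b_sync = b (1 - u)`` produces two identical daughters;
    ``b_async = b u`` produces one parental daughter and one daughter with a
    single new mutation, where ``u`` is the cell type's total transition
    probability.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"division probability b must be in [0, 1], got {b}")
    if not 0.0 <= u < 1.0:
        raise ValueError(f"total transition rate u must be in [0, 1), got {u}")
    return b * (1.0 - u), b * u


@dataclass(frozen=True)
class RateTriple:
    """Per-day event probabilities of one cell type: death, sync and async division."""

    b: float
    d: float
    b_sync: float
    b_async: float


def rate_triple(s: float, u: float) -> RateTriple:
    """Assemble the full per-day rate set for selection advantage ``s`` and
    total transition rate ``u``."""
    b = division_probability(s)
    d = death_probability(b)
    b_sync, b_async = split_division(b, u)
    return RateTriple(b=b, d=d, b_sync=b_sync, b_async=b_async)


# ---------------------------------------------------------------------------
# Transition structure
# ---------------------------------------------------------------------------


def enumerate_transitions(state: CellState, params: ModelParams) -> list[Transition]:
    """All single-mutation transitions available to ``state``.

    A cell with no sensitizing mutation can gain any one of the nine
    sensitizing mutations, or a platinum-resistance mechanism.  A cell
    already sensitized to gene G can only add resistance mechanisms — to
    platinum or to G's matched inhibitor (sensitivity precedes resistance;
    other inhibitors are irrelevant to a cell they cannot target).
    Transitions with zero probability are omitted.
    """
    out: list[Transition] = []
    if state.gene is Gene.NONE:
        for g in SENSITIZING_GENES:
            mu = params.mu_sens.get(g, 0.0)
            if mu > 0.0:
                out.append(Transition(state.with_sensitization(g), mu))
    else:
        mu_inh = params.mu_res.get(INHIBITOR_FOR[state.gene], 0.0)
        if mu_inh > 0.0:
            out.append(
                Transition(
                    state.with_extra_resistance(INHIBITOR_FOR[state.gene]), mu_inh
                )
            )
    mu_pt = params.mu_res.get(DrugClass.PT, 0.0)
    if mu_pt > 0.0:
        out.append(Transition(state.with_extra_resistance(DrugClass.PT), mu_pt))
    return out


def total_transition_rate(state: CellState, params: ModelParams) -> float:
    """Summed probability ``u`` of all transitions available to ``state``."""
    u = sum(t.prob for t in enumerate_transitions(state, params))
    if u >= 1.0:
        raise ValueError(
            f"total transition rate u={u} >= 1 for {state!r}; rates mis-configured"
        )
    return u
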