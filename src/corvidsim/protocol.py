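"""Experimental protocols as programs over the cage environment.

A protocol is a program of experimenter actions (add/remove food and trays,
cover/uncover, degrade, pilfer, wait, count) executed independently for each
bird, followed by an aggregation stage that fills a declared measurement
schema: per-group means and standard errors of recorded per-bird quantities,
plus p-values of declared statistical tests.  The result is a summary
dataset -- the unit compared against published results during fitting.

Protocols can be written directly as host-language functions against the
session interface, or, for linear (loop-free) designs, as declarative
YAML/JSON documents that this module interprets.  The declarative form
round-trips: serialize, re-parse, and the execution under a fixed seed is
identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .objects import CageEnvironment, FoodItem, InspectionObserver, Tray
from .simulator import Session


# ---------------------------------------------------------------------------
# summary datasets
# ---------------------------------------------------------------------------

@dataclass
class SummaryDataset:
    """Measured quantities of one (simulated or observed) experiment run.

    ``values`` maps quantity names to numbers; names in ``pvalue_names``
    form the p-value index set, the rest (means, SEMs, counts) the
    non-p-value index set.
    """

    experiment: str
    values: dict[str, float]
    pvalue_names: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.pvalue_names = frozenset(self.pvalue_names)
        for name in self.pvalue_names:
            p = self.values[name]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value {name}={p} outside [0, 1]")

    @property
    def quantity_names(self) -> frozenset[str]:
        return frozenset(self.values) - self.pvalue_names

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"experiment": self.experiment, "group": "",
             "quantity_name": k, "value": v,
             "is_pvalue": k in self.pvalue_names}
            for k, v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SummaryDataset":
        exp = df["experiment"].iloc[0] if len(df) else ""
        values = dict(zip(df["quantity_name"], df["value"].astype(float)))
        pnames = frozenset(df.loc[df["is_pvalue"].astype(bool), "quantity_name"])
        return cls(exp, values, pnames)

    @classmethod
    def from_csv(cls, path) -> "SummaryDataset":
        return cls.from_frame(pd.read_csv(path))


def mean_dataset(datasets: list[SummaryDataset]) -> SummaryDataset:
    """Entry-wise average of summary datasets (medians for p-values)."""
    first = datasets[0]
    values = {}
    for name in first.values:
        col = np.array([d.values[name] for d in datasets], dtype=float)
        if name in first.pvalue_names:
            values[name] = float(np.median(col))
        else:
            values[name] = float(np.nanmean(col))
    return SummaryDataset(first.experiment, values, first.pvalue_names)


# ---------------------------------------------------------------------------
# statistical test registry
# ---------------------------------------------------------------------------

def _clean_p(p: float) -> float:
    # degenerate data (zero variance, too few birds) yields nan: report 1.0,
    # i.e. no evidence against the null
    return 1.0 if (p is None or math.isnan(p)) else float(min(max(p, 0.0), 1.0))


def _mean(xs) -> float:
    return sum(xs) / len(xs)


def _sem(xs) -> float:
    n = len(xs)
    if n < 2:
        return 0.0
    m = _mean(xs)
    var = sum((x - m) ** 2 for x in xs) / (n - 1)
    return math.sqrt(var / n)


def paired_t(a, b) -> float:
    """Two-sided paired t-test (direct formula; scipy-equivalent)."""
    diffs = [x - y for x, y in zip(a, b)]
    n = len(diffs)
    se = _sem(diffs)
    if n < 2 or se == 0.0:
        return 1.0
    t = _mean(diffs) / se
    return _clean_p(2.0 * sps.t.sf(abs(t), n - 1))


def independent_t(a, b) -> float:
    """Two-sided pooled-variance two-sample t-test (scipy-equivalent)."""
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return 1.0
    ma, mb = _mean(a), _mean(b)
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    if sp2 == 0.0:
        return 1.0
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return _clean_p(2.0 * sps.t.sf(abs(t), df))


def sign_test(a, b) -> float:
    """Exact binomial test on the sign of per-bird differences (ties dropped)."""
    diffs = [x - y for x, y in zip(a, b) if x != y]
    if not diffs:
        return 1.0
    k = sum(d > 0 for d in diffs)
    return _clean_p(sps.binomtest(k, len(diffs), 0.5).pvalue)


def one_way_anova(*groups) -> float:
    return _clean_p(sps.f_oneway(*groups).pvalue)


TESTS = {
    "paired_t": paired_t,
    "independent_t": independent_t,
    "sign": sign_test,
    "anova": one_way_anova,
}


# ---------------------------------------------------------------------------
# declarative protocols
# ---------------------------------------------------------------------------

class ProtocolError(ValueError):
    pass


@dataclass
class Protocol:
    """A named experiment: group sizes, food repertoire, program, schema.

    ``spec`` is the declarative document (dict) interpreted per bird by
    :meth:`run`.  ``measurements`` declare the aggregation schema; every
    schema entry is produced exactly once per run.
    """

    name: str
    group_sizes: dict[str, int]
    food_types: tuple[str, ...]
    spec: dict = field(default_factory=dict)
    series: bool = False  # birds persist across sub-experiments of a series

    # -- serialization round-trip -----------------------------------------
    @classmethod
    def from_dict(cls, doc: dict) -> "Protocol":
        return cls(
            name=doc["name"],
            group_sizes={g: int(n) for g, n in doc["groups"].items()},
            food_types=tuple(doc["foods"]),
            spec=doc,
            series=bool(doc.get("series", False)),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "Protocol":
        return cls.from_dict(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.spec, sort_keys=False)

    @property
    def measurements(self) -> list[dict]:
        return self.spec["measurements"]

    @property
    def schema_names(self) -> list[str]:
        return [m["name"] for m in self.measurements]

    @property
    def pvalue_names(self) -> frozenset[str]:
        return frozenset(m["name"] for m in self.measurements if "test" in m)

    # -- execution ---------------------------------------------------------
    def run(self, birds_by_group: dict[str, list], rng) -> SummaryDataset:
        for group, n in self.group_sizes.items():
            if group not in birds_by_group:
                raise ProtocolError(f"missing group {group!r}")
        records: dict[str, list[dict[str, float]]] = {}
        for group, birds in birds_by_group.items():
            records[group] = []
            for bird in birds:
                session = Session(bird)
                self._run_bird(session, group)
                records[group].append(session.records)
        return self._aggregate(records)

    def _run_bird(self, session: Session, group: str) -> None:
        trays = self.spec.get("trays", {})
        for step in self.spec["steps"]:
            if "groups" in step and group not in step["groups"]:
                continue
            apply_step(session, step, trays)

    def _aggregate(self, records) -> SummaryDataset:
        values: dict[str, float] = {}
        for m in self.measurements:
            name = m["name"]
            if name in values:
                raise ProtocolError(f"duplicate measurement {name!r}")
            if "stat" in m:
                vals = [r[m["of"]] for r in records[m["group"]]]
                if m["stat"] == "mean":
                    values[name] = _mean(vals)
                elif m["stat"] == "sem":
                    values[name] = _sem(vals)
                else:
                    raise ProtocolError(f"unknown stat {m['stat']!r}")
            elif "test" in m:
                test = TESTS[m["test"]]
                of = m["of"]
                if isinstance(of, list):  # within-group comparison of two records
                    group = m["group"]
                    a = [r[of[0]] for r in records[group]]
                    b = [r[of[1]] for r in records[group]]
                    values[name] = test(a, b)
                else:  # across groups, one record
                    cols = [[r[of] for r in records[g]] for g in m["groups"]]
                    values[name] = test(*cols)
            else:
                raise ProtocolError(f"measurement {name!r} needs 'stat' or 'test'")
        missing = [n for n in self.schema_names if n not in values]
        if missing:
            raise ProtocolError(f"schema not filled: {missing}")
        return SummaryDataset(self.name, values, self.pvalue_names)


def _find_tray(session: Session, trays: dict, name: str):
    app = trays[name]["appearance"]
    env_trays = session.env.trays
    if app in env_trays:
        return env_trays[app]
    store = session.__dict__.get("_tray_store", {})
    if app in store:
        return store[app]
    raise KeyError(f"no tray with appearance {app}")


def apply_step(session: Session, step: dict, trays: dict) -> None:
    """Interpret one declarative protocol step on a session."""
    env = session.env
    action = step["action"]
    if action == "wait":
        session.wait(float(step["minutes"]))
    elif action == "add_food":
        env.add_food(FoodItem(step["food"], amount=int(step.get("amount", 1))))
    elif action == "remove_food":
        env.remove_food(step.get("food"))
    elif action == "add_tray":
        t = trays[step["tray"]]
        app = int(t["appearance"])
        # trays persist across remove/add cycles (taken out of the cage and
        # returned later with their caches intact)
        store = session.__dict__.setdefault("_tray_store", {})
        tray = store.get(app)
        if tray is None:
            tray = Tray(appearance=app, position=int(t["position"]))
            store[app] = tray
        tray.open = bool(step.get("open", True))
        env.add_tray(tray)
        session.note_tray_added(app)
    elif action == "remove_tray":
        app = trays[step["tray"]]["appearance"]
        session.note_tray_removed(app)
        env.remove_tray(app)
    elif action == "cover":
        tray = env.tray(trays[step["tray"]]["appearance"])
        if not tray.open:
            raise ProtocolError(f"tray {step['tray']} already covered")
        tray.open = False
    elif action == "uncover":
        env.tray(trays[step["tray"]]["appearance"]).open = True
    elif action == "degrade":
        # degrade/pilfer happen out of sight, possibly while the tray is
        # outside the cage: fall back to the session's tray store
        tray = _find_tray(session, trays, step["tray"])
        for item, _t in tray.cached:
            item.freshness = 0.0
    elif action == "pilfer":
        tray = _find_tray(session, trays, step["tray"])
        for item, _t in tray.cached:
            env.removed[item.food_type] = env.removed.get(item.food_type, 0) + 1
        tray.cached.clear()
    elif action == "move_caches":
        src = _find_tray(session, trays, step["from"])
        dst = _find_tray(session, trays, step["to"])
        dst.cached.extend(src.cached)
        src.cached.clear()
    elif action == "add_observer":
        apps = [trays[t]["appearance"] for t in step["trays"]]
        env.add_observer(InspectionObserver(step["name"], apps))
    elif action == "remove_observer":
        env.remove_observer(step["name"])
    elif action == "maintenance_diet":
        env.maintenance_diet = bool(step["present"])
    elif action == "record":
        _record(session, step, trays)
    else:
        raise ProtocolError(f"unknown action {action!r}")


def _record(session: Session, step: dict, trays: dict) -> None:
    env = session.env
    what = step["what"]
    if what == "cached_items":
        value = float(len(env.tray(trays[step["tray"]]["appearance"]).cached))
    elif what == "food_items":
        value = float(env.count_food_items())
    elif what == "eaten":
        value = float(env.eaten.get(step["food"], 0))
    elif what == "inspections":
        obs = env.observers[step["observer"]]
        value = float(obs.inspections()[trays[step["tray"]]["appearance"]])
    elif what == "first_inspection":
        obs = env.observers[step["observer"]]
        first = obs.first_inspection()
        value = float("nan") if first is None else float(first)
    else:
        raise ProtocolError(f"unknown record target {what!r}")
    for other in step.get("minus", []) if isinstance(step.get("minus"), list) \
            else ([step["minus"]] if "minus" in step else []):
        value -= session.records[other]
    session.records[step["as"]] = value
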