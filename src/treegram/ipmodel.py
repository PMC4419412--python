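"""Lightweight MILP container shared by the ordered and unordered builders.

Holds named variables, constraints grouped into the formulation's families,
and a linear objective; converts to the ``scipy.optimize.milp`` data layout
and writes CPLEX-LP and free-MPS text exports with a frozen naming scheme so
models can be audited or fed to external solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import sparse

__all__ = ["Variable", "Constraint", "IPModel"]


@dataclass
class Variable:
    name: str
    lb: float = 0.0
    ub: float = 1.0
    integer: bool = True
    kind: str = ""           # 'x' | 'y' | 'z' | 'p' | 's'
    meta: Any = None         # SubtreeRef for x, (ref, Split) for y/z, class key for p/s


@dataclass
class Constraint:
    name: str
    family: str              # e.g. 'eq1' .. 'eq12', 'eq11a', 'eq11b'
    terms: list[tuple[float, int]]
    sense: str               # '<=' or '='
    rhs: float


@dataclass
class IPModel:
    """Variables, constraints, and a minimized linear objective."""

    mode: str = "ordered"
    variables: list[Variable] = field(default_factory=list)
    constraints: list[Constraint] = field(default_factory=list)
    objective: dict[int, float] = field(default_factory=dict)
    by_name: dict[str, int] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    def add_var(self, name: str, kind: str, integer: bool = True,
                lb: float = 0.0, ub: float = 1.0, meta: Any = None) -> int:
        if name in self.by_name:
            raise ValueError(f"duplicate variable name {name!r}")
        idx = len(self.variables)
        self.variables.append(Variable(name, lb, ub, integer, kind, meta))
        self.by_name[name] = idx
        return idx

    def add_constr(self, name: str, family: str,
                   terms: Sequence[tuple[float, int]], sense: str,
                   rhs: float) -> None:
        if sense not in ("<=", "="):
            raise ValueError(f"unsupported sense {sense!r}")
        self.constraints.append(Constraint(name, family, list(terms), sense, rhs))

    def set_objective(self, terms: Sequence[tuple[float, int]]) -> None:
        self.objective = {i: c for c, i in terms}

    # -- introspection ------------------------------------------------------

    def stats(self) -> dict[str, dict[str, int]]:
        """Counts of variables by kind and constraints by formulation family."""
        vars_by_kind: dict[str, int] = {}
        for v in self.variables:
            vars_by_kind[v.kind] = vars_by_kind.get(v.kind, 0) + 1
        cons_by_family: dict[str, int] = {}
        for c in self.constraints:
            cons_by_family[c.family] = cons_by_family.get(c.family, 0) + 1
        return {"variables": vars_by_kind, "constraints": cons_by_family}

    # -- scipy layout -------------------------------------------------------

    def to_arrays(self):
        n = len(self.variables)
        c = np.zeros(n)
        for i, coef in self.objective.items():
            c[i] = coef
        integrality = np.array([1 if v.integer else 0 for v in self.variables])
        lb = np.array([v.lb for v in self.variables], dtype=float)
        ub = np.array([v.ub for v in self.variables], dtype=float)
        rows, cols, vals = [], [], []
        clb, cub = [], []
        for r, con in enumerate(self.constraints):
            for coef, i in con.terms:
                rows.append(r)
                cols.append(i)
                vals.append(coef)
            if con.sense == "<=":
                clb.append(-np.inf)
                cub.append(con.rhs)
            else:
                clb.append(con.rhs)
                cub.append(con.rhs)
        A = sparse.csr_matrix((vals, (rows, cols)),
                              shape=(len(self.constraints), n))
        return c, A, np.array(clb), np.array(cub), integrality, lb, ub

    # -- text exports -------------------------------------------------------

    @staticmethod
    def _lp_expr(terms: Sequence[tuple[float, int]], names: list[str]) -> str:
        parts = []
        for coef, i in terms:
            sign = "-" if coef < 0 else "+"
            mag = abs(coef)
            coef_s = "" if mag == 1 else (f"{int(mag)} " if mag == int(mag) else f"{mag} ")
            parts.append(f"{sign} {coef_s}{names[i]}")
        s = " ".join(parts)
        return s[2:] if s.startswith("+ ") else s

    def write_lp(self, path: str) -> None:
        """CPLEX-LP format export."""
        names = [v.name for v in self.variables]
        lines = ["Minimize", " obj: " + self._lp_expr(
            sorted(((c, i) for i, c in self.objective.items()), key=lambda t: t[1]),
            names)]
        lines.append("Subject To")
        for con in self.constraints:
            op = "<=" if con.sense == "<=" else "="
            rhs = int(con.rhs) if con.rhs == int(con.rhs) else con.rhs
            lines.append(f" {con.name}: {self._lp_expr(con.terms, names)} {op} {rhs}")
        lines.append("Bounds")
        for v in self.variables:
            if not v.integer or (v.lb, v.ub) != (0.0, 1.0):
                lines.append(f" {v.lb} <= {v.name} <= {v.ub}")
        bins = [v.name for v in self.variables if v.integer and (v.lb, v.ub) == (0.0, 1.0)]
        if bins:
            lines.append("Binaries")
            for name in bins:
                lines.append(f" {name}")
        gens = [v.name for v in self.variables if v.integer and (v.lb, v.ub) != (0.0, 1.0)]
        if gens:
            lines.append("Generals")
            for name in gens:
                lines.append(f" {name}")
        lines.append("End")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def write_mps(self, path: str) -> None:
        """Free-format MPS export."""
        names = [v.name for v in self.variables]
        out = ["NAME treegram", "ROWS", " N obj"]
        for con in self.constraints:
            out.append(f" {'L' if con.sense == '<=' else 'E'} {con.name}")
        out.append("COLUMNS")
        col_entries: dict[int, list[tuple[str, float]]] = {
            i: [] for i in range(len(names))}
        for i, coef in self.objective.items():
            col_entries[i].append(("obj", coef))
        for con in self.constraints:
            for coef, i in con.terms:
                col_entries[i].append((con.name, coef))
        for i, v in enumerate(self.variables):
            if v.integer:
                out.append(" MARKER 'MARKER' 'INTORG'")
            for row, coef in col_entries[i]:
                out.append(f" {v.name} {row} {coef}")
            if v.integer:
                out.append(" MARKER 'MARKER' 'INTEND'")
        out.append("RHS")
        for con in self.constraints:
            if con.rhs != 0:
                out.append(f" rhs {con.name} {con.rhs}")
        out.append("BOUNDS")
        for v in self.variables:
            out.append(f" LO bnd {v.name} {v.lb}")
            out.append(f" UP bnd {v.name} {v.ub}")
        out.append("ENDATA")
        with open(path, "w") as fh:
            fh.write("\n".join(out) + "\n")
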