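"""Quantitative food-web data model and I/O.

A quantitative food web is a directed network G = (V, E) whose nodes are
species (or trophic compartments) and whose edge weights w_ij carry the
carbon flux from species i to species j (gC m^-2 day^-1).  Besides the
inter-species flow matrix, each species carries three boundary vectors:
imports (flux received from outside the system), exports and respiration
(flux leaving the system).

Two plain-text formats are supported: a canonical JSON schema and a
flow-matrix TSV.  An adapter maps supplementary-style JSON files with
arbitrary key names onto the canonical schema via a YAML mapping.

Analyses run on the *augmented* web: a virtual environment node is attached
that feeds every importing species and absorbs exports + respiration.  The
environment node is never removable and never goes extinct; its only role
in the extinction model is that import edges persist when species die.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger("kweb")

__all__ = [
    "FoodWeb",
    "AugmentedWeb",
    "WebSummary",
    "FoodWebValidationError",
    "read_foodweb_json",
    "write_foodweb_json",
    "read_flow_matrix_tsv",
    "write_flow_matrix_tsv",
    "read_s1_json",
    "augment_with_environment",
    "summarize",
    "weighted_connectance",
]

#: Reserved trailing columns of the flow-matrix TSV format.
_TSV_RESERVED = ("import", "export", "respiration")

_JSON_KEYS = ("name", "species", "flows", "imports", "exports", "respiration")


class FoodWebValidationError(ValueError):
    """Raised when food-web data violates the schema or its invariants."""


def _as_vector(values, n: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise FoodWebValidationError(
            f"{what}: expected length-{n} vector, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise FoodWebValidationError(f"{what}: non-finite value")
    if np.any(arr < 0):
        raise FoodWebValidationError(f"{what}: negative value")
    return arr


@dataclass(frozen=True)
class FoodWeb:
    """An un-augmented quantitative food web.

    ``flows[i, j]`` is the energy flux from species ``i`` to species ``j``.
    The diagonal may be non-zero (cannibalism occurs in real webs) and such
    self-links count as links.
    """

    name: str
    species: tuple[str, ...]
    flows: np.ndarray
    imports: np.ndarray
    exports: np.ndarray
    respiration: np.ndarray

    def __post_init__(self) -> None:
        species = tuple(str(s) for s in self.species)
        n = len(species)
        if n < 1:
            raise FoodWebValidationError("species: need at least one species")
        if len(set(species)) != n:
            dupes = sorted({s for s in species if species.count(s) > 1})
            raise FoodWebValidationError(f"species: duplicate labels {dupes}")
        flows = np.asarray(self.flows, dtype=float)
        if flows.shape != (n, n):
            raise FoodWebValidationError(
                f"flows: expected {n}x{n} matrix, got shape {flows.shape}"
            )
        if not np.all(np.isfinite(flows)):
            raise FoodWebValidationError("flows: non-finite value")
        if np.any(flows < 0):
            raise FoodWebValidationError("flows: negative value")
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "flows", flows)
        object.__setattr__(self, "imports", _as_vector(self.imports, n, "imports"))
        object.__setattr__(self, "exports", _as_vector(self.exports, n, "exports"))
        object.__setattr__(
            self, "respiration", _as_vector(self.respiration, n, "respiration")
        )

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index_of(self, label: str) -> int:
        try:
            return self.species.index(label)
        except ValueError:
            raise KeyError(f"unknown species {label!r} in web {self.name!r}") from None

    def equals(self, other: "FoodWeb") -> bool:
        return (
            self.species == other.species
            and np.array_equal(self.flows, other.flows)
            and np.array_equal(self.imports, other.imports)
            and np.array_equal(self.exports, other.exports)
            and np.array_equal(self.respiration, other.respiration)
        )


@dataclass(frozen=True)
class AugmentedWeb:
    """A food web with the virtual environment node attached.

    ``env_out`` holds the environment->species weights (the imports) and
    ``env_in`` the species->environment weights (exports + respiration).
    ``baseline_inflow[i]`` caches the total inflow of species ``i`` in the
    intact web — the denominator of the survival fraction P(i).
    """

    base: FoodWeb
    env_out: np.ndarray
    env_in: np.ndarray
    baseline_inflow: np.ndarray

    @property
    def n_species(self) -> int:
        return self.base.n_species

    @property
    def species(self) -> tuple[str, ...]:
        return self.base.species


def augment_with_environment(web: FoodWeb) -> AugmentedWeb:
    """Attach the virtual environment node and cache baseline inflows.

    The environment feeds each species its import flux and absorbs its
    export + respiration flux.  Baseline inflow is imports plus the column
    sum of the inter-species flow matrix, evaluated on the intact web.
    Augmentation is idempotent: it never alters inter-species flows.
    """
    baseline = web.imports + web.flows.sum(axis=0)
    zero = np.flatnonzero(baseline == 0)
    if zero.size:
        labels = [web.species[i] for i in zero]
        logger.warning(
            "web %r: species with zero baseline inflow %s — treated as "
            "immediately non-viable in cascades (P(i) := 0)",
            web.name,
            labels,
        )
    return AugmentedWeb(
        base=web,
        env_out=web.imports.copy(),
        env_in=web.exports + web.respiration,
        baseline_inflow=baseline,
    )


# ---------------------------------------------------------------------------
# Canonical JSON
# ---------------------------------------------------------------------------

def _foodweb_from_mapping(data: dict, origin: str) -> FoodWeb:
    missing = [k for k in _JSON_KEYS if k != "name" and k not in data]
    if missing:
        raise FoodWebValidationError(f"{origin}: missing required key(s) {missing}")
    rows = data["flows"]
    if isinstance(rows, list) and len({len(r) for r in rows if isinstance(r, list)}) > 1:
        raise FoodWebValidationError(
            f"{origin}: flows is a ragged matrix "
            f"(row lengths {sorted({len(r) for r in rows})})"
        )
    return FoodWeb(
        name=str(data.get("name", origin)),
        species=tuple(data["species"]),
        flows=np.asarray(rows, dtype=float),
        imports=data["imports"],
        exports=data["exports"],
        respiration=data["respiration"],
    )


def read_foodweb_json(path: str | Path) -> FoodWeb:
    """Read a food web from the canonical JSON schema.

    Schema: ``{"name": str, "species": [str], "flows": [[float]]`` (row =
    source, column = target), ``"imports"/"exports"/"respiration": [float]}``.
    Species order is preserved from the file.
    """
    path = Path(path)
    with path.open() as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FoodWebValidationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, dict):
        raise FoodWebValidationError(f"{path}: top level must be a JSON object")
    return _foodweb_from_mapping(data, origin=path.stem)


def write_foodweb_json(web: FoodWeb, path: str | Path) -> None:
    """Write a food web in the canonical JSON schema."""
    payload = {
        "name": web.name,
        "species": list(web.species),
        "flows": web.flows.tolist(),
        "imports": web.imports.tolist(),
        "exports": web.exports.tolist(),
        "respiration": web.respiration.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Flow-matrix TSV
# ---------------------------------------------------------------------------

def read_flow_matrix_tsv(path: str | Path) -> FoodWeb:
    """Read a food web from a flow-matrix TSV.

    First row and first column carry species labels; the trailing reserved
    columns ``import``, ``export`` and ``respiration`` carry the boundary
    vectors.  Equivalent content yields a web equal to the JSON reader's.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FoodWebValidationError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 1 + len(_TSV_RESERVED):
        raise FoodWebValidationError(f"{path}: header too short: {header}")
    if tuple(header[-3:]) != _TSV_RESERVED:
        raise FoodWebValidationError(
            f"{path}: trailing header columns must be {_TSV_RESERVED}, got {header[-3:]}"
        )
    species = header[1:-3]
    n = len(species)
    if len(lines) - 1 != n:
        raise FoodWebValidationError(
            f"{path}: header names {n} species but file has {len(lines) - 1} data rows"
        )
    flows = np.zeros((n, n))
    imports = np.zeros(n)
    exports = np.zeros(n)
    respiration = np.zeros(n)
    for r, line in enumerate(lines[1:]):
        cells = line.split("\t")
        if len(cells) != n + 4:
            raise FoodWebValidationError(
                f"{path}: row {r + 2} has {len(cells)} cells, expected {n + 4}"
            )
        if cells[0] != species[r]:
            raise FoodWebValidationError(
                f"{path}: row {r + 2} label {cells[0]!r} does not match "
                f"header species {species[r]!r}"
            )
        for c, cell in enumerate(cells[1:], start=2):
            try:
                value = float(cell)
            except ValueError:
                raise FoodWebValidationError(
                    f"{path}: non-numeric cell {cell!r} at row {r + 2}, column {c}"
                ) from None
            if c - 2 < n:
                flows[r, c - 2] = value
            else:
                (imports, exports, respiration)[c - 2 - n][r] = value
    return FoodWeb(
        name=path.stem,
        species=tuple(species),
        flows=flows,
        imports=imports,
        exports=exports,
        respiration=respiration,
    )


def write_flow_matrix_tsv(web: FoodWeb, path: str | Path) -> None:
    """Write a food web in the flow-matrix TSV format."""
    out = ["\t".join(["species", *web.species, *_TSV_RESERVED])]
    for i, sp in enumerate(web.species):
        row = [sp]
        row += [repr(float(v)) for v in web.flows[i]]
        row += [
            repr(float(web.imports[i])),
            repr(float(web.exports[i])),
            repr(float(web.respiration[i])),
        ]
        out.append("\t".join(row))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Supplementary-data adapter
# ---------------------------------------------------------------------------

def read_s1_json(path: str | Path, mapping: str | Path | dict) -> FoodWeb:
    """Read a supplementary-style JSON file through a key-mapping config.

    ``mapping`` is a YAML file (or dict) whose keys are the canonical field
    names (``species``, ``flows``, ``imports``, ``exports``, ``respiration``,
    optionally ``name``) and whose values are the key names used in the
    source file.  Unknown structure fails loudly rather than guessing.
    """
    if not isinstance(mapping, dict):
        mapping = yaml.safe_load(Path(mapping).read_text())
    if not isinstance(mapping, dict):
        raise FoodWebValidationError("mapping config must be a mapping")
    path = Path(path)
    with path.open() as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise FoodWebValidationError(f"{path}: top level must be a JSON object")
    canonical: dict = {}
    for key in _JSON_KEYS:
        src = mapping.get(key, key if key == "name" else None)
        if src is None:
            raise FoodWebValidationError(f"mapping config: no source key for {key!r}")
        if src in data:
            canonical[key] = data[src]
        elif key != "name":
            raise FoodWebValidationError(
                f"{path}: source key {src!r} (for canonical {key!r}) not found; "
                f"available keys: {sorted(data)}"
            )
    return _foodweb_from_mapping(canonical, origin=path.stem)


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WebSummary:
    """Species count S, link count C_n, connectance C = C_n/S^2, and the
    entropy-based weighted directed connectance C_w."""

    S: int
    C_n: int
    C: float
    C_w: float


def _link_count(web: FoodWeb) -> int:
    # strictly positive inter-species flows, self-links included,
    # environment edges excluded
    return int(np.count_nonzero(web.flows > 0))


def summarize(web: FoodWeb) -> WebSummary:
    """Descriptive statistics of a web: S, C_n, C and C_w."""
    s = web.n_species
    c_n = _link_count(web)
    return WebSummary(S=s, C_n=c_n, C=c_n / s**2, C_w=weighted_connectance(web))


def weighted_connectance(web: FoodWeb) -> float:
    """Weighted directed connectance from Shannon-entropy effective links.

    Each species' inflow and outflow distributions over the inter-species
    flow matrix are reduced to effective prey / predator counts exp(H)
    (the perplexity of the flux distribution); the weighted link density is
    their average over 2S, and C_w is that density divided by S.  When all
    L links carry identical weight this reduces to the binary connectance
    L/S^2.  Returns 0 for a web with no inter-species flow.  Display-only:
    no algorithm consumes this number.
    """
    w = web.flows
    s = web.n_species
    if not np.any(w > 0):
        return 0.0

    def effective(counts: np.ndarray) -> float:
        # sum over species of exp(entropy of its flux distribution)
        total = 0.0
        for row in counts:
            m = row.sum()
            if m <= 0:
                continue
            p = row[row > 0] / m
            total += math.exp(-(p * np.log(p)).sum())
        return total

    eff_links = 0.5 * (effective(w) + effective(w.T))  # out- and in-side views
    return eff_links / s**2
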