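"""Readers and writers for the pipeline's delimited-text artifacts.

All CSVs use UTF-8, comma separators and ``.`` decimals regardless of
locale; floats are serialized with 17 significant digits so a write/read
round trip is bit-exact.  The run configuration is a validated dataclass
loadable from YAML or JSON.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gravity import FlowProbabilityMatrix
from .network import SupplyNetwork
from .outbreak import Outbreak
from .region import Brand, Region, Store, Zone

__all__ = [
    "SchemaError",
    "ReferentialIntegrityError",
    "ConfigError",
    "RunConfig",
    "read_region",
    "write_region",
    "read_matrix",
    "write_matrix",
    "write_calibration_report",
    "write_network",
    "read_network",
    "write_outbreaks",
    "read_outbreaks",
    "flow_probabilities_from_file",
    "configure_logging",
]

_FLOAT_FMT = "%.17g"

ZONES_COLUMNS = ["zone_id", "x_km", "y_km", "area_km2", "population"]
STORES_COLUMNS = ["store_id", "brand_id", "zone_id", "revenue"]
BRANDS_COLUMNS = ["brand_id", "total_revenue"]


class SchemaError(ValueError):
    """A file does not match its declared tabular schema."""


class ReferentialIntegrityError(ValueError):
    """A row references a zone or brand that does not exist."""


class ConfigError(ValueError):
    """A run-configuration value is out of range."""


def configure_logging(level: int = logging.INFO) -> None:
    """One structured line per pipeline stage on stderr."""
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All generator, calibration, simulation and evaluation parameters."""

    # synthetic region
    n_zones: int = 49
    n_brands: int = 10
    bbox_km: float = 25.0
    pop_range: tuple[float, float] = (2_000.0, 30_000.0)
    stores_per_brand_range: tuple[int, int] = (3, 15)
    revenue_range: tuple[float, float] = (3.0e7, 4.0e8)
    # cost matrix / calibration
    intrazonal_method: str = "lattice"
    target_mean_km: float = 4.65
    furness_tol: float = 1e-6
    furness_max_iter: int = 10_000
    hyman_tol_km: float = 0.01
    hyman_max_outer: int = 50
    thresholds: tuple[float, ...] = (0.0, 0.05, 0.10)
    # outbreak simulation / evaluation
    scenarios: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45, 49)
    n_outbreaks: int = 300  # 1000 reproduces the full experiment
    n_ill: int = 500
    n_unique: int = 20  # default scenario for the simulate/infer commands
    illness_grid: tuple[int, ...] = (1, 2, 5, 10, 20, 30, 50, 100, 200, 500)
    seed: int = 7

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_zones < 2 or self.n_brands < 1:
            raise ConfigError("n_zones >= 2 and n_brands >= 1 required")
        for name in ("bbox_km", "target_mean_km", "furness_tol", "hyman_tol_km"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("furness_max_iter", "hyman_max_outer", "n_outbreaks", "n_ill"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.intrazonal_method not in ("lattice", "circle"):
            raise ConfigError("intrazonal_method must be 'lattice' or 'circle'")
        if any(not (0 <= t < 1) for t in self.thresholds):
            raise ConfigError("thresholds must lie in [0, 1)")
        if any(s < 1 for s in self.scenarios):
            raise ConfigError("scenario sizes must be >= 1")
        if any(m < 1 or m > self.n_ill for m in self.illness_grid):
            raise ConfigError("illness_grid values must be in [1, n_ill]")
        if not (1 <= self.n_unique <= self.n_ill):
            raise ConfigError("n_unique must be in [1, n_ill]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pop_range", "stores_per_brand_range", "revenue_range",
                    "thresholds", "scenarios", "illness_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Region tables
# ---------------------------------------------------------------------------


def _read_csv(path: Path, columns: list[str], optional: set[str] = frozenset()) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={c: str for c in columns if c.endswith("_id")},
        float_precision="round_trip",
    )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path.name}: no rows")
    return df


def write_region(region: Region, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(z.zone_id, z.x, z.y, z.area, z.population) for z in region.zones],
        columns=ZONES_COLUMNS,
    ).to_csv(directory / "zones.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [(s.store_id, s.brand_id, s.zone_id, s.revenue) for s in region.stores],
        columns=STORES_COLUMNS,
    ).to_csv(directory / "stores.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [(b.brand_id, b.total_revenue) for b in region.brands],
        columns=BRANDS_COLUMNS,
    ).to_csv(directory / "brands.csv", index=False, float_format=_FLOAT_FMT)


def read_region(directory: str | Path) -> Region:
    """Read zones.csv, stores.csv and brands.csv from a directory.

    If stores.csv carries an optional ``weight`` column, each brand's total
    revenue is apportioned over its stores proportionally to the weights,
    overriding the stored per-store revenues (stand-in for store-size data).
    """
    directory = Path(directory)
    zones_df = _read_csv(directory / "zones.csv", ZONES_COLUMNS)
    stores_df = _read_csv(directory / "stores.csv", STORES_COLUMNS)
    brands_df = _read_csv(directory / "brands.csv", BRANDS_COLUMNS)

    zones = [
        Zone(r.zone_id, float(r.x_km), float(r.y_km), float(r.area_km2), float(r.population))
        for r in zones_df.itertuples()
    ]
    brands = [Brand(r.brand_id, float(r.total_revenue)) for r in brands_df.itertuples()]
    zone_ids = {z.zone_id for z in zones}
    brand_ids = {b.brand_id: b for b in brands}
    for r in stores_df.itertuples():
        if r.zone_id not in zone_ids:
            raise ReferentialIntegrityError(
                f"stores.csv: store {r.store_id} references unknown zone {r.zone_id}"
            )
        if r.brand_id not in brand_ids:
            raise ReferentialIntegrityError(
                f"stores.csv: store {r.store_id} references unknown brand {r.brand_id}"
            )
    if "weight" in stores_df.columns:
        w = stores_df["weight"].astype(float)
        if (w <= 0).any():
            raise SchemaError("stores.csv: weights must be positive")
        brand_w = w.groupby(stores_df["brand_id"]).transform("sum")
        revenue = (
            stores_df["brand_id"].map(lambda b: brand_ids[b].total_revenue)
            * w / brand_w
        )
    else:
        revenue = stores_df["revenue"].astype(float)
    stores = [
        Store(r.store_id, r.brand_id, r.zone_id, float(rev))
        for r, rev in zip(stores_df.itertuples(), revenue)
    ]
    return Region(zones=zones, brands=brands, stores=stores)


# ---------------------------------------------------------------------------
# Labeled square matrices (costs, flows, flow probabilities)
# ---------------------------------------------------------------------------


def write_matrix(values: np.ndarray, labels: list[str], path: str | Path,
                 float_format: str = _FLOAT_FMT) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(
        Path(path), float_format=float_format, index_label="zone_id"
    )


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(Path(path), index_col=0, float_precision="round_trip")
    labels = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if labels != cols:
        raise SchemaError(f"{Path(path).name}: row labels differ from column labels")
    return labels, df.to_numpy(dtype=float)


def write_calibration_report(path: str | Path, *, beta: float, iterations: int,
                             mean_km: float, max_marginal_error: float) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "beta_per_km": beta,
                "furness_iterations": iterations,
                "mean_flow_distance_km": mean_km,
                "max_marginal_error": max_marginal_error,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Networks and outbreaks
# ---------------------------------------------------------------------------


def write_network(net: SupplyNetwork, directory: str | Path, label: str) -> None:
    """Edge-list CSV (src_id, dst_id, prob) plus a JSON node-partition header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tids = net.transient_ids
    aids = [f"consume:{z}" for z in net.absorbing_ids]
    rows = []
    for i, src in enumerate(tids):
        for j, dst in enumerate(tids):
            if net.P_Q[i, j] > 0:
                rows.append((src, dst, net.P_Q[i, j]))
        for j, dst in enumerate(aids):
            if net.P_R[i, j] > 0:
                rows.append((src, dst, net.P_R[i, j]))
    pd.DataFrame(rows, columns=["src_id", "dst_id", "prob"]).to_csv(
        directory / f"network_{label}_edges.csv", index=False, float_format=_FLOAT_FMT
    )
    (directory / f"network_{label}_nodes.json").write_text(
        json.dumps(
            {
                "brands": net.brand_ids,
                "retailer_zones": net.retailer_zone_ids,
                "consumer_zones": net.consumer_zone_ids,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )


def read_network(directory: str | Path, label: str) -> SupplyNetwork:
    directory = Path(directory)
    parts = json.loads((directory / f"network_{label}_nodes.json").read_text())
    edges = pd.read_csv(directory / f"network_{label}_edges.csv")
    brands = list(parts["brands"])
    retail = list(parts["retailer_zones"])
    consume = list(parts["consumer_zones"])
    nb, nr, nc = len(brands), len(retail), len(consume)
    tidx = {b: k for k, b in enumerate(brands)}
    tidx.update({f"retail:{z}": nb + k for k, z in enumerate(retail)})
    aidx = {f"consume:{z}": k for k, z in enumerate(consume)}
    P_Q = np.zeros((nb + nr, nb + nr))
    P_R = np.zeros((nb + nr, nc))
    for r in edges.itertuples():
        if r.src_id not in tidx:
            raise SchemaError(f"edge source {r.src_id!r} not a transient node")
        if r.dst_id in tidx:
            P_Q[tidx[r.src_id], tidx[r.dst_id]] = r.prob
        elif r.dst_id in aidx:
            P_R[tidx[r.src_id], aidx[r.dst_id]] = r.prob
        else:
            raise SchemaError(f"edge target {r.dst_id!r} not a known node")
    return SupplyNetwork(
        brand_ids=brands, retailer_zone_ids=retail, consumer_zone_ids=consume,
        P_Q=P_Q, P_R=P_R,
    )


def write_outbreaks(outbreaks: list[Outbreak], path: str | Path) -> None:
    from .outbreak import outbreaks_to_frame

    outbreaks_to_frame(outbreaks).to_csv(Path(path), index=False)


def read_outbreaks(path: str | Path) -> list[Outbreak]:
    df = pd.read_csv(Path(path), dtype={"true_source": str, "zone_id": str})
    for col in ("outbreak_id", "true_source", "zone_id", "illness_index"):
        if col not in df.columns:
            raise SchemaError(f"{Path(path).name}: missing column {col}")
    out = []
    for _, grp in df.groupby("outbreak_id", sort=True):
        grp = grp.sort_values("illness_index")
        sources = grp["true_source"].unique()
        if len(sources) != 1:
            raise SchemaError("an outbreak must have a single true source")
        out.append(Outbreak(true_source=sources[0], observations=list(grp["zone_id"])))
    return out


def flow_probabilities_from_file(path: str | Path) -> FlowProbabilityMatrix:
    labels, P = read_matrix(path)
    return FlowProbabilityMatrix(
        zone_ids=labels, P=P, zero_rows=P.sum(axis=1) <= 0
    )
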