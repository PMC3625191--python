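"""On-disk artifacts, canonical feature indexing and run configuration.

Every delimited file the package reads or writes is tab-separated UTF-8.
Tables (manifest, atlas, score tables) carry a header row; numeric grids
(time series, connectivity matrices) are headerless.  Region indices are
1-based in files, matching atlas conventions, and converted to 0-based
array indices at this boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("fcmvpa")

__all__ = [
    "FeatureIndex",
    "feature_index",
    "ManifestEntry",
    "SubjectManifest",
    "load_manifest",
    "write_manifest",
    "AtlasTable",
    "load_atlas",
    "write_atlas",
    "RunConfig",
    "load_config",
    "write_config",
    "rng_from",
]


# ---------------------------------------------------------------------------
# Feature indexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureIndex:
    """Bijection between feature positions and region pairs.

    A symmetric R x R connectivity matrix carries R(R-1)/2 informative
    entries; they are vectorized in row-major upper-triangle order
    (1,2), (1,3), ..., (1,R), (2,3), ..., (R-1,R).  ``rows``/``cols`` are
    the 0-based array indices of each feature position; the public pair
    accessors speak 1-based region indices.
    """

    n_regions: int
    rows: np.ndarray
    cols: np.ndarray

    def __len__(self) -> int:
        return self.rows.shape[0]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """All (i, j) region pairs, 1-based, in feature order."""
        return list(zip((self.rows + 1).tolist(), (self.cols + 1).tolist()))

    def position(self, i: int, j: int) -> int:
        """Feature position of the 1-based region pair (i, j), i < j."""
        r = self.n_regions
        if not (1 <= i < j <= r):
            raise ValueError(f"invalid region pair ({i}, {j}) for R={r}")
        return (i - 1) * r - i * (i - 1) // 2 + (j - i - 1)

    def pair(self, position: int) -> tuple[int, int]:
        """1-based region pair at a feature position."""
        if not (0 <= position < len(self)):
            raise ValueError(f"feature position {position} out of range")
        return int(self.rows[position]) + 1, int(self.cols[position]) + 1

    def pair_name(self, position: int, atlas: "AtlasTable | None" = None) -> str:
        i, j = self.pair(position)
        if atlas is None:
            return f"{i}-{j}"
        return f"{atlas.name_of(i)}/{atlas.name_of(j)}"


def feature_index(n_regions: int) -> FeatureIndex:
    """Canonical upper-triangle feature index for an R-region parcellation.

    For the 116-region AAL parcellation this yields 6670 features.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions to form a connectivity feature")
    rows, cols = np.triu_indices(n_regions, k=1)
    return FeatureIndex(n_regions=int(n_regions), rows=rows, cols=cols)


# ---------------------------------------------------------------------------
# Subject manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    label: int  # +1 control, -1 patient
    data_path: Path
    nuisance_path: Path | None = None


@dataclass(frozen=True)
class SubjectManifest:
    entries: tuple[ManifestEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def subject_ids(self) -> list[str]:
        return [e.subject_id for e in self.entries]

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.entries], dtype=int)

    def group_sizes(self) -> tuple[int, int]:
        """(n positive, n negative) subject counts."""
        y = self.labels
        return int((y == 1).sum()), int((y == -1).sum())


def load_manifest(path: str | Path, check_files: bool = True) -> SubjectManifest:
    """Read a subject manifest TSV (columns subject_id, label, data_path,
    optional nuisance_path); file paths resolve relative to the manifest."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    for col in ("subject_id", "label", "data_path"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} is missing required column {col!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id in manifest: {sorted(set(dup))}")
    bad = set(df["label"].astype(int)) - {1, -1}
    if bad:
        raise ValueError(f"labels must be +1 or -1, got {sorted(bad)}")

    base = path.parent
    entries = []
    for row in df.itertuples(index=False):
        data_path = base / str(row.data_path)
        nuis = getattr(row, "nuisance_path", None)
        nuis_path = None
        if nuis is not None and not pd.isna(nuis) and str(nuis):
            nuis_path = base / str(nuis)
        if check_files:
            if not data_path.is_file():
                raise FileNotFoundError(
                    f"data file for subject {row.subject_id!r} not found: {data_path}"
                )
            if nuis_path is not None and not nuis_path.is_file():
                raise FileNotFoundError(
                    f"nuisance file for subject {row.subject_id!r} not found: {nuis_path}"
                )
        entries.append(
            ManifestEntry(str(row.subject_id), int(row.label), data_path, nuis_path)
        )
    return SubjectManifest(entries=tuple(entries))


def write_manifest(manifest: SubjectManifest, path: str | Path) -> None:
    path = Path(path)
    base = path.parent

    def rel(p: Path | None) -> str:
        if p is None:
            return ""
        try:
            return str(Path(p).relative_to(base))
        except ValueError:
            return str(p)

    df = pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in manifest.entries],
            "label": [e.label for e in manifest.entries],
            "data_path": [rel(e.data_path) for e in manifest.entries],
            "nuisance_path": [rel(e.nuisance_path) for e in manifest.entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Atlas lookup table
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class AtlasTable:
    """Region lookup table: 1-based region index -> name and network."""

    region_names: tuple[str, ...]
    network_ids: np.ndarray  # 1-based network id per region
    network_names: tuple[str, ...]  # indexed by network id - 1

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AtlasTable)
            and self.region_names == other.region_names
            and np.array_equal(self.network_ids, other.network_ids)
            and self.network_names == other.network_names
        )

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def name_of(self, region_index: int) -> str:
        return self.region_names[region_index - 1]

    def network_of(self, region_index: int) -> int:
        return int(self.network_ids[region_index - 1])

    def network_name_of(self, network_id: int) -> str:
        return self.network_names[network_id - 1]

    def region_index_of(self, name: str) -> int:
        try:
            return self.region_names.index(name) + 1
        except ValueError:
            raise KeyError(f"region {name!r} not in atlas") from None


def load_atlas(path: str | Path) -> AtlasTable:
    """Read an atlas TSV with columns region_index, region_name, network_id,
    network_name.  Region indices must be contiguous from 1."""
    df = pd.read_csv(path, sep="\t")
    for col in ("region_index", "region_name", "network_id", "network_name"):
        if col not in df.columns:
            raise ValueError(f"atlas {path} is missing required column {col!r}")
    df = df.sort_values("region_index")
    idx = df["region_index"].to_numpy(dtype=int)
    if not np.array_equal(idx, np.arange(1, len(df) + 1)):
        raise ValueError("atlas region indices must be contiguous from 1")
    net_ids = df["network_id"].to_numpy(dtype=int)
    n_networks = int(net_ids.max())
    network_names: list[str] = [""] * n_networks
    for nid, nname in zip(net_ids, df["network_name"].astype(str)):
        if network_names[nid - 1] and network_names[nid - 1] != nname:
            raise ValueError(f"conflicting names for network {nid}")
        network_names[nid - 1] = nname
    return AtlasTable(
        region_names=tuple(df["region_name"].astype(str)),
        network_ids=net_ids,
        network_names=tuple(network_names),
    )


def write_atlas(atlas: AtlasTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "region_index": np.arange(1, atlas.n_regions + 1),
            "region_name": list(atlas.region_names),
            "network_id": atlas.network_ids,
            "network_name": [atlas.network_name_of(i) for i in atlas.network_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable parameters of one classification run.

    The defaults are the operating point of the reference analysis: a
    0.01-0.08 Hz Chebyshev type-I band-pass, the top 22 connectivity
    features by Kendall-tau discriminative power, an 8-neighbor LLE into
    10 dimensions and an RBF-SVM with C = 2.
    """

    # band-pass filter
    low_hz: float = 0.01
    high_hz: float = 0.08
    tr: float = 2.0
    filter_order: int = 5
    filter_ripple_db: float = 0.1
    # feature selection
    n_features: int = 22
    # embedding
    reducer: str = "lle"  # "lle" | "pca" | "none"
    n_neighbors: int = 8
    n_components: int = 10
    lle_reg: float = 1e-3
    # classifier
    classifier: str = "svm"  # "svm" | "lda" | "cmeans"
    svm_c: float = 2.0
    svm_gamma: float | str = "scale"  # "scale" = 1 / (d * var(X_train))
    cmeans_m: float = 2.0
    lda_ridge: float = 1e-6
    # evaluation
    n_permutations: int = 10000
    retention_min: int = 51
    ss_convention: str = "patient"  # which class the "sensitivity" name reports
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= 0.5 / self.tr:
            raise ValueError(
                f"high_hz={self.high_hz} exceeds the Nyquist frequency "
                f"{0.5 / self.tr:.4g} Hz for TR={self.tr}"
            )
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_neighbors < 1 or self.n_components < 1:
            raise ValueError("n_neighbors and n_components must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("permutation count must be >= 1")
        if self.reducer not in ("lle", "pca", "none"):
            raise ValueError(f"unknown reducer {self.reducer!r}")
        if self.classifier not in ("svm", "lda", "cmeans"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.ss_convention not in ("patient", "printed"):
            raise ValueError("ss_convention must be 'patient' or 'printed'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a RunConfig from a flat TOML key-value file; keyword arguments
    override file values (the CLI maps flags onto these)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    lines = []
    for key, value in cfg.to_dict().items():
        if isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        elif isinstance(value, bool):
            lines.append(f"{key} = {str(value).lower()}")
        else:
            lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def rng_from(seed_or_cfg: int | RunConfig | np.random.Generator) -> np.random.Generator:
    """Single entry point for randomness: every stochastic component draws
    from a generator produced here, so one integer seed fixes a run."""
    if isinstance(seed_or_cfg, np.random.Generator):
        return seed_or_cfg
    if isinstance(seed_or_cfg, RunConfig):
        return np.random.default_rng(seed_or_cfg.seed)
    return np.random.default_rng(int(seed_or_cfg))
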