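"""Core data containers for the pipeline.

The pipeline operates on three aligned tables: an ASV (amplicon sequence
variant) count table with per-sample collection dates and depth labels, a
taxonomy table holding PR2-style eight-rank lineages, and a table of
environmental/biological covariates.  The taxonomy container also derives
the matching keys used for interaction-database lookups (genus, Syndiniales
group, radiolarian host class, MAST clade), since several protist groups are
not resolvable to genus level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANK_NAMES = (
    "domain",
    "supergroup",
    "division",
    "subdivision",
    "class",
    "order",
    "family",
    "genus",
)

#: closed set of interaction types used by PIDA-style databases
INTERACTION_TYPES = ("parasitism", "predation", "symbiosis", "unresolved")

#: the ranks at which a database record key may be expressed
MATCH_RANKS = ("genus", "syndiniales_group", "radiolarian_class", "mast_clade")


def norm_key(key: str) -> str:
    """Normalize a taxon key: case-insensitive, separator- and
    whitespace-insensitive.  Used for every database comparison."""
    return " ".join(re.sub(r"[-_]+", " ", str(key)).lower().split())


def genus_key(genus: str) -> str:
    """Normalized genus key; strain/species suffixes are ignored
    (``"Teleaulax amphioxeia"`` and ``"Teleaulax"`` compare equal)."""
    toks = norm_key(genus).split()
    return toks[0] if toks else ""


_SYND_RE = re.compile(r"(?:dino|syndiniales)\s+group\s+(i{1,3}|iv|v)\b")
_MAST_RE = re.compile(r"\bmast\s+(\d+[a-z]?)\b")


@dataclass
class AsvTable:
    """Samples-by-ASVs abundance matrix plus per-sample metadata.

    ``counts`` is a DataFrame indexed by sample id with ASV ids as columns;
    values are nonnegative (read counts or relative abundances).  ``dates``
    and ``depth`` are Series aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    dates: pd.Series
    depth: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate ASV ids: {dup}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("counts contain non-finite values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                "negative abundance at sample "
                f"{self.counts.index[i]!r}, ASV {self.counts.columns[j]!r}"
            )
        self.dates = pd.to_datetime(self.dates).reindex(self.counts.index)
        if self.dates.isna().any():
            missing = self.dates.index[self.dates.isna()].tolist()
            raise ValueError(f"missing/unparseable dates for samples: {missing}")
        self.depth = self.depth.reindex(self.counts.index).astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_depth(self, depth: str) -> "AsvTable":
        keep = self.depth == depth
        if not keep.any():
            raise ValueError(f"no samples with depth label {depth!r}")
        return AsvTable(self.counts.loc[keep], self.dates[keep], self.depth[keep])

    def subset_asvs(self, asv_ids) -> "AsvTable":
        return AsvTable(self.counts.loc[:, list(asv_ids)], self.dates, self.depth)


@dataclass
class TaxonomyTable:
    """ASV id -> eight-rank lineage (domain..genus, optional species), with
    derived database-matching keys.

    ``lineages`` maps each ASV id to a list of 8 or 9 rank strings.  The
    derived per-ASV keys are:

    genus
        normalized genus key, or ``""`` when the lineage has no genus-level
        resolution (common for Syndiniales and MAST clades).
    syndiniales_group
        e.g. ``"group ii"`` for lineages within the parasitic Syndiniales,
        whose sub-group taxonomy is unresolved and is matched at group level.
    radiolarian_class
        ``"acantharea clade f"`` or ``"polycystinea"`` for radiolarian hosts
        matched at host-class level.
    mast_clade
        e.g. ``"mast 3e"`` for marine stramenopile clades.
    """

    lineages: dict[str, list[str]]
    keys: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = {}
        for asv, lin in self.lineages.items():
            if len(lin) not in (8, 9):
                raise ValueError(
                    f"lineage for {asv!r} has {len(lin)} ranks, expected 8 or 9"
                )
            rows[asv] = self._derive_keys(lin)
        self.keys = pd.DataFrame.from_dict(rows, orient="index")

    @staticmethod
    def _derive_keys(lineage: list[str]) -> dict[str, str]:
        joined = norm_key(";".join(lineage)).replace(";", " ")
        m = _SYND_RE.search(joined)
        synd = f"group {m.group(1)}" if m else ""
        # a lineage lists both "MAST-3" and "MAST-3E"; keep the most specific
        mast_hits = [m.group(1) for m in _MAST_RE.finditer(joined)]
        mast = f"mast {max(mast_hits, key=len)}" if mast_hits else ""
        cls = norm_key(lineage[4])
        rad = ""
        if "acantharea" in joined and "clade f" in joined:
            rad = "acantharea clade f"
        elif cls.startswith("polycystin"):
            rad = "polycystinea"
        genus = genus_key(lineage[7]) if len(lineage) >= 8 else ""
        return {
            "genus": genus,
            "syndiniales_group": synd,
            "radiolarian_class": rad,
            "mast_clade": mast,
        }

    @property
    def asv_ids(self) -> list[str]:
        return list(self.lineages)

    def match_keys(self, asv_id: str) -> list[tuple[str, str]]:
        """All (rank, key) pairs under which this ASV can match a database
        record, special ranks first (they take precedence over genus)."""
        row = self.keys.loc[asv_id]
        out = []
        for rank in ("syndiniales_group", "radiolarian_class", "mast_clade"):
            if row[rank]:
                out.append((rank, row[rank]))
        if row["genus"]:
            out.append(("genus", row["genus"]))
        return out

    def lineage_string(self, asv_id: str) -> str:
        return ";".join(self.lineages[asv_id])


@dataclass
class EnvTable:
    """Samples-by-variables matrix of environmental/biological covariates.

    Missing entries are NaN until imputation; ``standardized`` records
    whether columns have been centered/scaled to mean 0, variance 1.
    """

    values: pd.DataFrame
    standardized: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def check_complete(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing values remain in variables: {bad}")
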