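"""Match network edges against a curated protist-interaction database.

Literature-curated interaction databases (PIDA-style) record pairwise
interactions between taxa, typed as predation, parasitism, symbiosis
(mutualism) or "unresolved".  Amplicon-derived ASVs, however, often lack
genus-level resolution, so matching uses four taxonomy-aware rules:

1. Syndiniales parasites match at the Syndiniales *group* level paired with
   the host genus.
2. Radiolarian photosymbioses match at the host-class level (Acantharea
   Clade F, or polycystines) paired with the symbiont genus.
3. MAST symbioses match at the MAST *clade* level paired with the symbiont
   genus.
4. Everything else matches genus-to-genus.

Special rules take precedence over the genus rule wherever a lineage
qualifies.  Database types "symbiosis" and "unresolved" are reported under
a single "other_symbioses" category.  Edges with no database support are
"novel" and are ranked by the Spearman correlation (SCC) of the partners'
CLR abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import INTERACTION_TYPES, MATCH_RANKS, TaxonomyTable, norm_key

#: database type -> reported category ("unresolved" folds into symbioses)
REPORTED_TYPE = {
    "parasitism": "parasitism",
    "predation": "predation",
    "symbiosis": "other_symbioses",
    "unresolved": "other_symbioses",
}
REPORTED_CATEGORIES = ("parasitism", "predation", "other_symbioses")

#: which (rank_a, rank_b) combinations each matching rule covers
_RULE_OF_RANKS = {
    frozenset({"syndiniales_group", "genus"}): "syndiniales_group_host_genus",
    frozenset({"radiolarian_class", "genus"}): "radiolarian_class_symbiont_genus",
    frozenset({"mast_clade", "genus"}): "mast_clade_symbiont_genus",
    frozenset({"genus"}): "genus_genus",
}
RULE_PRECEDENCE = (
    "syndiniales_group_host_genus",
    "radiolarian_class_symbiont_genus",
    "mast_clade_symbiont_genus",
    "genus_genus",
)


@dataclass(frozen=True)
class DBRecord:
    record_id: str
    taxon_a_key: str
    taxon_a_rank: str
    taxon_b_key: str
    taxon_b_rank: str
    interaction_type: str
    multiplicity: int = 1

    def key_pair(self) -> frozenset:
        return frozenset(
            {(self.taxon_a_rank, norm_key(self.taxon_a_key)),
             (self.taxon_b_rank, norm_key(self.taxon_b_key))}
        )


@dataclass
class InteractionDB:
    """A set of typed taxon-pair records plus a provenance string."""

    records: list[DBRecord]
    provenance: str = ""
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.interaction_type not in INTERACTION_TYPES:
                raise ValueError(f"unknown interaction type {r.interaction_type!r}")
            if r.taxon_a_rank not in MATCH_RANKS or r.taxon_b_rank not in MATCH_RANKS:
                raise ValueError(f"unknown rank in record {r.record_id}")
            if not r.taxon_a_key or not r.taxon_b_key:
                raise ValueError(f"empty taxon key in record {r.record_id}")
        self._index = {}
        for r in self.records:
            self._index.setdefault(r.key_pair(), []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, pair: frozenset) -> list[DBRecord]:
        return self._index.get(pair, [])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def parse_interaction_db(path, provenance: str = "") -> InteractionDB:
    """Read a TSV of interaction records, validating types and ranks.

    Exact duplicates (same keys, ranks and type) are collapsed into one
    record whose ``multiplicity`` is the duplicate count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"record_id", "taxon_a_key", "taxon_a_rank",
                "taxon_b_key", "taxon_b_rank", "interaction_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["interaction_type"] not in INTERACTION_TYPES:
            raise ValueError(
                f"line {line}: unknown interaction type {row['interaction_type']!r}"
            )
        for c in ("taxon_a_rank", "taxon_b_rank"):
            if row[c] not in MATCH_RANKS:
                raise ValueError(f"line {line}: unknown rank {row[c]!r}")
    seen: dict[tuple, DBRecord] = {}
    for _, row in df.iterrows():
        sig = (
            frozenset({(row["taxon_a_rank"], norm_key(row["taxon_a_key"])),
                       (row["taxon_b_rank"], norm_key(row["taxon_b_key"]))}),
            row["interaction_type"],
        )
        if sig in seen:
            old = seen[sig]
            seen[sig] = DBRecord(**{**vars(old), "multiplicity": old.multiplicity + 1})
        else:
            seen[sig] = DBRecord(
                record_id=row["record_id"],
                taxon_a_key=row["taxon_a_key"],
                taxon_a_rank=row["taxon_a_rank"],
                taxon_b_key=row["taxon_b_key"],
                taxon_b_rank=row["taxon_b_rank"],
                interaction_type=row["interaction_type"],
            )
    return InteractionDB(list(seen.values()), provenance=provenance)


def write_interaction_db(db: InteractionDB, path) -> None:
    rows = db.to_frame()
    cols = ["record_id", "taxon_a_key", "taxon_a_rank",
            "taxon_b_key", "taxon_b_rank", "interaction_type"]
    rows[cols].to_csv(path, sep="\t", index=False)


@dataclass
class EdgeAnnotation:
    edge: tuple[str, str]
    status: str  # "supported" | "novel"
    matched_records: list[str] = field(default_factory=list)
    reported_types: tuple[str, ...] = ()
    match_rule: str = ""
    reason: str = ""
    scc: float = np.nan
    partial_corr: float = np.nan


def match_edges(
    edges,
    taxonomy: TaxonomyTable,
    db: InteractionDB,
    partial_corrs: dict | None = None,
) -> list[EdgeAnnotation]:
    """Annotate each edge as database-supported or novel.

    ``edges`` is an iterable of unordered ASV-id pairs.  Matching is
    symmetric in the pair order: both orderings of the ASVs' candidate keys
    are tried against each record.  An edge may match several records (the
    same Syndiniales group-host record can support many ASV-level edges);
    all matches are kept and every matched type is reported, with
    "symbiosis" and "unresolved" folded into "other_symbioses".
    """
    partial_corrs = partial_corrs or {}
    out = []
    for a, b in edges:
        for asv in (a, b):
            if asv not in taxonomy.lineages:
                raise KeyError(f"ASV {asv!r} missing from taxonomy")
        edge = tuple(sorted((a, b)))
        keys_a = taxonomy.match_keys(a)
        keys_b = taxonomy.match_keys(b)
        pc = partial_corrs.get(frozenset(edge), np.nan)
        if not keys_a or not keys_b:
            out.append(EdgeAnnotation(edge, "novel", reason="rank-unresolvable",
                                      partial_corr=pc))
            continue
        hits: list[tuple[str, DBRecord]] = []
        for ra, ka in keys_a:
            for rb, kb in keys_b:
                rule = _RULE_OF_RANKS.get(frozenset({ra, rb}))
                if rule is None:
                    continue
                pair = frozenset({(ra, ka), (rb, kb)})
                for rec in db.lookup(pair):
                    hits.append((rule, rec))
        if hits:
            hits.sort(key=lambda h: RULE_PRECEDENCE.index(h[0]))
            types = tuple(sorted({REPORTED_TYPE[rec.interaction_type]
                                  for _, rec in hits}))
            out.append(EdgeAnnotation(
                edge, "supported",
                matched_records=[rec.record_id for _, rec in hits],
                reported_types=types,
                match_rule=hits[0][0],
                partial_corr=pc,
            ))
        else:
            out.append(EdgeAnnotation(edge, "novel", reason="no-matching-record",
                                      partial_corr=pc))
    return out


def summarize_recall(
    annotations: list[EdgeAnnotation],
    db: InteractionDB,
    taxonomy: TaxonomyTable,
    network_input_asvs,
) -> pd.DataFrame:
    """Recall summary per reported category: how many database records
    exist, how many have both partners realizable by at least one ASV in
    the network input, and how many supported edges the network found.
    """
    input_keys = set()
    for asv in network_input_asvs:
        input_keys.update(taxonomy.match_keys(asv))
    rows = {}
    for cat in REPORTED_CATEGORIES:
        recs = [r for r in db.records if REPORTED_TYPE[r.interaction_type] == cat]
        realizable = [
            r for r in recs
            if (r.taxon_a_rank, norm_key(r.taxon_a_key)) in input_keys
            and (r.taxon_b_rank, norm_key(r.taxon_b_key)) in input_keys
        ]
        found = [a for a in annotations
                 if a.status == "supported" and cat in a.reported_types]
        rows[cat] = {
            "db_records": len(recs),
            "db_records_both_present": len(realizable),
            "supported_edges_found": len(found),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def novel_edge_scc(
    annotations: list[EdgeAnnotation],
    clr_matrix: pd.DataFrame,
    report_threshold: float = 0.64,
    which: str = "novel",
) -> pd.DataFrame:
    """Spearman correlation of CLR abundances for each (by default novel)
    edge, ranked by |SCC|; |SCC| >= threshold is flagged "strong".

    Constant CLR series make the rank correlation undefined; such edges are
    flagged and excluded from the ranking.
    """
    rows, dropped = [], []
    for ann in annotations:
        if which != "all" and ann.status != which:
            continue
        a, b = ann.edge
        x = clr_matrix[a].to_numpy()
        y = clr_matrix[b].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            dropped.append(ann.edge)
            ann.scc = np.nan
            ann.reason = (ann.reason + ";scc-undefined").strip(";")
            continue
        scc = stats.spearmanr(x, y).statistic
        ann.scc = scc
        rows.append({"asv_a": a, "asv_b": b, "scc": scc,
                     "abs_scc": abs(scc), "strong": abs(scc) >= report_threshold})
    table = pd.DataFrame(rows, columns=["asv_a", "asv_b", "scc", "abs_scc", "strong"])
    table = table.sort_values("abs_scc", ascending=False, kind="mergesort")
    if dropped:
        warnings.warn(f"SCC undefined (constant series) for {len(dropped)} edges")
    return table.reset_index(drop=True)


def annotations_to_frame(annotations: list[EdgeAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "asv_a": a.edge[0], "asv_b": a.edge[1], "status": a.status,
            "match_rule": a.match_rule,
            "reported_types": ";".join(a.reported_types),
            "matched_records": ";".join(a.matched_records),
            "reason": a.reason, "scc": a.scc, "partial_corr": a.partial_corr,
        } for a in annotations]
    )
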