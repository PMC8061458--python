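"""Controlled-vocabulary label learning from free-text sample metadata.

GEO-style SOFT blocks are parsed into ordered key:value records; a rule table
of case-insensitive regular expressions (shipped as an editable TSV, one rule
per row) maps the raw text onto controlled-vocabulary terms per category.
Single-valued categories (sex, age, storage) resolve by priority — conflicting
matches at equal priority withhold the value rather than guess; multi-valued
categories (tissue, disease/group) accumulate all matching terms. Numeric age
capture normalizes units to years (months / 12, weeks / 52).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "MetadataRecord",
    "VocabularyRule",
    "HarmonizedLabels",
    "load_default_rules",
    "parse_soft_block",
    "apply_vocabulary",
    "cohort_coverage",
]

MULTI_VALUED = frozenset({"tissue", "disease/group"})
SINGLE_VALUED = frozenset({"sex", "age", "storage"})


@dataclass
class MetadataRecord:
    sample_id: str
    study_id: str | None
    fields: list  # ordered (key, value) pairs, raw text


@dataclass(frozen=True)
class VocabularyRule:
    category: str
    term: str
    pattern: str
    priority: int
    kind: str = "presence"  # or "numeric"

    def __post_init__(self) -> None:
        if self.category not in MULTI_VALUED | SINGLE_VALUED:
            raise ValueError(f"unknown category {self.category!r}")
        if self.kind not in ("presence", "numeric"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        re.compile(self.pattern, re.IGNORECASE)  # must compile

    @property
    def regex(self):
        return re.compile(self.pattern, re.IGNORECASE)


@dataclass
class HarmonizedLabels:
    sample_id: str
    terms: dict = field(default_factory=dict)  # category -> set of terms
    age_years: float | None = None
    provenance: list = field(default_factory=list)  # (category, term, rule idx, key)
    conflicts: list = field(default_factory=list)


def load_rules(path_or_stream) -> list[VocabularyRule]:
    tab = pd.read_csv(path_or_stream, sep="\t")
    return [
        VocabularyRule(
            category=r.category,
            term=r.term,
            pattern=r.pattern,
            priority=int(r.priority),
            kind=r.kind,
        )
        for r in tab.itertuples()
    ]


def load_default_rules() -> list[VocabularyRule]:
    ref = resources.files("methcompass.data") / "vocabulary_rules.tsv"
    with ref.open() as fh:
        return load_rules(fh)


def parse_soft_block(text: str) -> MetadataRecord:
    """Parse one SOFT-style sample block.

    Keys keep their SOFT names minus the ``!Sample_`` prefix; repeated keys
    are preserved in order; characteristics lines split once on the first
    colon into ``characteristics.<subkey>``.
    """
    sample_id, study_id = None, None
    fields: list = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("^SAMPLE"):
            sample_id = line.split("=", 1)[1].strip() if "=" in line else None
            continue
        if "=" not in line:
            continue
        key, value = (part.strip() for part in line.split("=", 1))
        key = key.lstrip("!")
        if key.startswith("Sample_"):
            key = key[len("Sample_"):]
        if key == "geo_accession" and sample_id is None:
            sample_id = value
        if key == "series_id":
            study_id = value
        if key.startswith("characteristics") and ":" in value:
            sub, val = value.split(":", 1)
            fields.append((f"characteristics.{sub.strip()}", val.strip()))
        else:
            fields.append((key, value))
    if not fields:
        raise ValueError("no parseable SOFT lines")
    return MetadataRecord(sample_id=sample_id or "", study_id=study_id, fields=fields)


_UNIT_DIVISOR = {
    None: 1.0, "": 1.0,
    "year": 1.0, "years": 1.0, "yr": 1.0, "yrs": 1.0, "y": 1.0,
    "month": 12.0, "months": 12.0, "mo": 12.0, "mos": 12.0,
    "week": 52.0, "weeks": 52.0, "wk": 52.0, "wks": 52.0,
}


def _scan_text(record: MetadataRecord):
    """Yield the text snippets rules are matched against.

    Characteristics sub-keys are folded back in ('age (yrs): 34') so patterns
    can anchor on the key as well as the value.
    """
    for key, value in record.fields:
        if key.startswith("characteristics."):
            yield key, f"{key[len('characteristics.'):]}: {value}"
        else:
            yield key, value


def apply_vocabulary(
    record: MetadataRecord, rules: list[VocabularyRule] | None = None
) -> HarmonizedLabels:
    """Scan every field with every rule and assemble per-category labels."""
    rules = rules if rules is not None else load_default_rules()
    labels = HarmonizedLabels(sample_id=record.sample_id)
    # category -> term -> (best priority, provenance)
    matches: dict = {}
    numeric: dict = {}
    for rule_idx, rule in enumerate(rules):
        rx = rule.regex
        for key, text in _scan_text(record):
            m = rx.search(text)
            if not m:
                continue
            if rule.kind == "numeric":
                raw = float(m.group(1))
                unit = (m.group(2) or "").strip().lower() if m.lastindex and m.lastindex >= 2 else ""
                value = raw / _UNIT_DIVISOR.get(unit, 1.0)
                entry = numeric.setdefault(rule.category, [])
                entry.append((rule.priority, value, rule_idx, key))
            else:
                entry = matches.setdefault(rule.category, {})
                prev = entry.get(rule.term)
                if prev is None or rule.priority > prev[0]:
                    entry[rule.term] = (rule.priority, rule_idx, key)

    for category, terms in matches.items():
        if category in MULTI_VALUED:
            labels.terms[category] = set(terms)
            labels.provenance.extend(
                (category, t, idx, key) for t, (_, idx, key) in terms.items()
            )
        else:
            best = max(p for p, _, _ in terms.values())
            winners = [t for t, (p, _, _) in terms.items() if p == best]
            if len(winners) > 1:
                labels.conflicts.append((category, sorted(winners)))
                continue
            term = winners[0]
            labels.terms[category] = {term}
            _, idx, key = terms[term]
            labels.provenance.append((category, term, idx, key))

    for category, entries in numeric.items():
        best = max(p for p, _, _, _ in entries)
        distinct = sorted({round(v, 6) for p, v, _, _ in entries if p == best})
        if len(distinct) > 1:
            labels.conflicts.append((category, distinct))
            continue
        value = next(v for p, v, _, _ in entries if p == best)
        if category == "age":
            if value < 0:
                labels.conflicts.append((category, [value]))
                continue
            labels.age_years = value
        p, v, idx, key = next(e for e in entries if e[0] == best)
        labels.provenance.append((category, value, idx, key))
    return labels


def cohort_coverage(labels: list[HarmonizedLabels]) -> dict:
    """Count/fraction of samples labeled per category and per term."""
    n = len(labels)
    cat_counts: dict = {}
    term_counts: dict = {}
    term_samples: dict = {}
    for lab in labels:
        seen_cats = set(lab.terms)
        if lab.age_years is not None:
            seen_cats.add("age")
        for cat in seen_cats:
            cat_counts[cat] = cat_counts.get(cat, 0) + 1
        for cat, terms in lab.terms.items():
            for term in terms:
                term_counts[(cat, term)] = term_counts.get((cat, term), 0) + 1
                term_samples.setdefault((cat, term), set()).add(lab.sample_id)
    categories = pd.DataFrame(
        {
            "count": pd.Series(cat_counts, dtype=int),
            "fraction": pd.Series({k: v / n for k, v in cat_counts.items()})
            if n
            else pd.Series(dtype=float),
        }
    )
    terms = pd.DataFrame(
        [
            {"category": c, "term": t, "count": v, "fraction": v / n}
            for (c, t), v in sorted(term_counts.items())
        ]
    )
    keys = sorted(term_samples)
    overlap = pd.DataFrame(
        [
            [len(term_samples[a] & term_samples[b]) for b in keys]
            for a in keys
        ],
        index=pd.Index([f"{c}:{t}" for c, t in keys]),
        columns=pd.Index([f"{c}:{t}" for c, t in keys]),
    )
    return {"n_samples": n, "categories": categories, "terms": terms, "overlap": overlap}
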