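"""Readers/writers for the tabular exchange formats.

Three plain-text formats:

* transactions — one row per protein: the item codes (one per feature,
  whitespace-separated) followed by an optional parenthesized class label,
  e.g. ``1 4 16 ... 109 (E)``;
* rules — one row per rule: hit-rate, hit-number, the antecedent codes,
  a rule label like ``(C1)``, and the target class ``(C)``;
* predictions — id, predicted class (or ABSTAIN), hit-rate, and the
  winning rule's items.

Any run of whitespace separates fields on read; writes are tab-separated.
Class labels and rule labels are accepted with or without parentheses and
written with them.  Models round-trip through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence

from ._transactions import Transaction, TransactionDB
from .classify import ABSTAIN, PredictionResult
from .rule_mining import MultiClassModel, Rule, RuleMiningParams, RuleSet
from .schema import FeatureSchema


class ParseError(ValueError):
    """A malformed row, annotated with its 1-based line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _strip_parens(token: str) -> str:
    if token.startswith("(") and token.endswith(")"):
        return token[1:-1]
    return token


def _is_label(token: str) -> bool:
    body = _strip_parens(token)
    return bool(body) and not body.lstrip("-").isdigit()


def read_transactions(path, schema: Optional[FeatureSchema] = None,
                      ) -> TransactionDB:
    """Read a transactions table; validate against ``schema`` when given.

    Labeled and unlabeled rows may be mixed (unlabeled rows are prediction
    input).  With a schema, every row must carry exactly one in-range code
    per feature.
    """
    rows: List[Transaction] = []
    valid_labels = set(schema.class_labels) if schema else None
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            label = None
            if _is_label(tokens[-1]):
                label = _strip_parens(tokens.pop())
            try:
                codes = [int(tok) for tok in tokens]
            except ValueError as e:
                raise ParseError(path, line_no, f"non-integer item code: {e}")
            if not codes:
                raise ParseError(path, line_no, "row has no item codes")
            t = Transaction(f"L{line_no}", codes, label)
            if schema is not None:
                if label is not None and valid_labels and label not in valid_labels:
                    raise ParseError(
                        path, line_no,
                        f"label {label!r} not in {sorted(valid_labels)}")
                if len(codes) != schema.n_features:
                    raise ParseError(
                        path, line_no,
                        f"{len(codes)} codes for {schema.n_features} features")
                try:
                    schema.validate_transaction(t)
                except ValueError as e:
                    raise ParseError(path, line_no, str(e))
            rows.append(t)
    return TransactionDB(rows)


def write_transactions(db: TransactionDB, path) -> None:
    with open(path, "w") as fh:
        for t in db:
            codes = sorted(t.items)
            line = "\t".join(str(c) for c in codes)
            if t.label is not None:
                line += f"\t({t.label})"
            fh.write(line + "\n")


@dataclass(frozen=True)
class RulesFileRow:
    """One row of a rules table."""

    hit_rate: float
    hit_number: int
    items: tuple
    rule_label: str
    location: str

    def to_rule(self) -> Rule:
        positives = int(round(self.hit_rate * self.hit_number))
        return Rule(self.items, self.location, self.hit_number, positives)


def _format_hit_rate(x: float) -> str:
    return f"{x:.3f}"


def read_rules(path) -> List[RulesFileRow]:
    """Parse a rules table (hit-rate, hit-number, items..., label, class)."""
    out: List[RulesFileRow] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 5:
                raise ParseError(path, line_no, f"expected >= 5 fields, got {len(tokens)}")
            try:
                hit_rate = float(tokens[0])
                hit_number = int(tokens[1])
                items = tuple(int(tok) for tok in tokens[2:-2])
            except ValueError as e:
                raise ParseError(path, line_no, f"malformed rule row: {e}")
            if not 0 <= hit_rate <= 1:
                raise ParseError(path, line_no, f"hit-rate {hit_rate} outside [0, 1]")
            out.append(
                RulesFileRow(
                    hit_rate, hit_number, items,
                    _strip_parens(tokens[-2]), _strip_parens(tokens[-1]),
                )
            )
    return out


def write_rules(rows: Sequence[RulesFileRow], path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        _format_hit_rate(r.hit_rate),
                        str(r.hit_number),
                        " ".join(str(i) for i in r.items),
                        f"({r.rule_label})",
                        f"({r.location})",
                    ]
                )
                + "\n"
            )


def model_rules_rows(model: MultiClassModel) -> List[RulesFileRow]:
    """Flatten a model into rules-table rows, labeled C1, C2, ... per class."""
    rows = []
    for tag in model.class_order:
        for k, rule in enumerate(model.rulesets[tag], 1):
            rows.append(
                RulesFileRow(
                    rule.hit_rate, rule.hits, rule.sorted_items(),
                    f"{tag}{k}", tag,
                )
            )
    return rows


def write_predictions(results: Sequence[PredictionResult], path) -> None:
    """Write predictions: id, class (or ABSTAIN), hit-rate, rule items."""
    with open(path, "w") as fh:
        fh.write("#id\tprediction\thit_rate\trule_items\n")
        for r in results:
            if r.predicted == ABSTAIN:
                fh.write(f"{r.id}\t{ABSTAIN}\t-\t-\n")
            else:
                items = " ".join(str(i) for i in r.matched_rule.sorted_items())
                fh.write(
                    f"{r.id}\t({r.predicted})\t"
                    f"{_format_hit_rate(r.confidence)}\t{items}\n"
                )


# ---------------------------------------------------------------------------
# Model persistence (JSON)

def save_model(model: MultiClassModel, path) -> None:
    payload = {
        "params": {
            "min_support": model.params.min_support,
            "min_hit_rate": model.params.min_hit_rate,
            "max_loops": model.params.max_loops,
            "mining_scope": model.params.mining_scope,
            "selection_policy": model.params.selection_policy,
            "min_antecedent_len": model.params.min_antecedent_len,
        },
        "class_order": model.class_order,
        "schema_ref": model.schema_ref,
        "bin_edges_snapshot": model.bin_edges_snapshot,
        "rulesets": {
            tag: [
                {
                    "antecedent": sorted(r.antecedent),
                    "hits": r.hits,
                    "positives": r.positives,
                    "loop_index": r.loop_index,
                }
                for r in model.rulesets[tag]
            ]
            for tag in model.class_order
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> MultiClassModel:
    with open(path) as fh:
        payload = json.load(fh)
    params = RuleMiningParams(**payload["params"])
    rulesets = {
        tag: RuleSet(
            tag,
            [
                Rule(frozenset(r["antecedent"]), tag, r["hits"],
                     r["positives"], r.get("loop_index", 0))
                for r in rows
            ],
            params,
        )
        for tag, rows in payload["rulesets"].items()
    }
    return MultiClassModel(
        rulesets, params,
        class_order=payload["class_order"],
        schema_ref=payload.get("schema_ref"),
        bin_edges_snapshot=payload.get("bin_edges_snapshot"),
    )
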