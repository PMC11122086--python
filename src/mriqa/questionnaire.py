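"""Subjective image-quality questionnaire: schema, validation, text round trip.

The subjective rating is the one mandatory part of an assessment.  A schema
is pure data (ordered items with ordinal / multi-select / free-text answer
kinds and conditional-display rules), so questionnaires for other body parts
or modalities are configurable without code changes.  The default schema
targets multi-parametric breast MRI: an unconditional overall impression on a
five-level scale, and — unless the overall impression is "excellent" —
detail items on contrast adequacy, noise level, and an artifact checklist
including fat-suppression failure and metal-clip artifacts.

Responses serialize to a human-readable UTF-8 key-value text file (the file
dropped into the ``IQA`` output folder) and parse back losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

__all__ = [
    "QuestionnaireItem", "QuestionnaireSchema", "QuestionnaireResponse",
    "default_schema", "validate_response", "serialize_response",
    "parse_response", "load_schema", "save_schema", "blank_response_template",
]

ANSWER_KINDS = ("ordinal", "multiselect", "text")


@dataclass(frozen=True)
class QuestionnaireItem:
    id: str
    prompt: str
    kind: str                                  # one of ANSWER_KINDS
    levels: tuple[str, ...] = ()               # ordinal scale labels
    options: tuple[str, ...] = ()              # multiselect choices
    show_if: Optional[tuple[str, str, str]] = None   # (item id, "eq"|"ne", value)

    def __post_init__(self) -> None:
        if self.kind not in ANSWER_KINDS:
            raise ValueError(f"unknown answer kind {self.kind!r}")
        if self.kind == "ordinal" and len(self.levels) < 2:
            raise ValueError(f"ordinal item {self.id!r} needs >= 2 levels")
        if self.kind == "multiselect" and not self.options:
            raise ValueError(f"multiselect item {self.id!r} needs options")
        if self.show_if is not None and self.show_if[1] not in ("eq", "ne"):
            raise ValueError("show_if operator must be 'eq' or 'ne'")


@dataclass(frozen=True)
class QuestionnaireSchema:
    id: str
    items: tuple[QuestionnaireItem, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for item in self.items:
            if item.id in seen:
                raise ValueError(f"duplicate item id {item.id!r}")
            if item.show_if is not None and item.show_if[0] not in seen:
                raise ValueError(
                    f"item {item.id!r} conditional rule references "
                    f"{item.show_if[0]!r}, which is not an earlier item"
                )
            seen.add(item.id)

    def item(self, item_id: str) -> QuestionnaireItem:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)


@dataclass
class QuestionnaireResponse:
    """One rater's answers; ``overall`` is mandatory, details conditional."""

    schema_id: str
    series_id: str = ""
    timestamp: str = ""
    answers: dict = field(default_factory=dict)   # item id -> str | list[str]
    comment: str = ""


def default_schema() -> QuestionnaireSchema:
    """The breast-MRI schema shipped with the tool.

    Item wording is the package's own reconstruction around the attributes a
    breast protocol stresses (overall impression, contrast, noise, fat
    suppression, metal clips, motion); replace via a schema file for other
    use cases.
    """
    quality_levels = ("excellent", "good", "moderate", "poor", "non-diagnostic")
    not_excellent = ("overall", "ne", "excellent")
    return QuestionnaireSchema(
        id="breast_mp_mri_v1",
        items=(
            QuestionnaireItem(
                id="overall",
                prompt="Overall impression of image quality",
                kind="ordinal", levels=quality_levels),
            QuestionnaireItem(
                id="contrast",
                prompt="Adequacy of tissue contrast",
                kind="ordinal",
                levels=("adequate", "borderline", "inadequate"),
                show_if=not_excellent),
            QuestionnaireItem(
                id="noise",
                prompt="Perceived noise level",
                kind="ordinal",
                levels=("low", "moderate", "high"),
                show_if=not_excellent),
            QuestionnaireItem(
                id="artifacts",
                prompt="Artifacts present (select all that apply)",
                kind="multiselect",
                options=("fat suppression failure", "metal clip artifact",
                         "motion", "ghosting", "other"),
                show_if=not_excellent),
            QuestionnaireItem(
                id="comments",
                prompt="Free-text comments",
                kind="text"),
        ),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _rule_fires(rule: Optional[tuple[str, str, str]], answers: dict) -> bool:
    if rule is None:
        return True
    ref, op, value = rule
    answered = answers.get(ref)
    return (answered == value) if op == "eq" else (answered != value)


def validate_response(response: QuestionnaireResponse,
                      schema: QuestionnaireSchema) -> list[str]:
    """Return the list of violations (empty means the response is valid)."""
    violations: list[str] = []
    if response.schema_id != schema.id:
        violations.append(
            f"response schema {response.schema_id!r} != {schema.id!r}")
    if not response.answers.get("overall"):
        violations.append("mandatory item absent: overall")

    item_ids = {it.id for it in schema.items}
    for item_id in response.answers:
        if item_id not in item_ids:
            violations.append(f"answer for unknown item {item_id!r}")

    for item in schema.items:
        answer = response.answers.get(item.id)
        fires = _rule_fires(item.show_if, response.answers)
        if answer is None:
            continue
        if not fires:
            violations.append(
                f"item {item.id!r} answered although its display rule "
                f"{item.show_if} does not fire")
            continue
        if item.kind == "ordinal" and answer not in item.levels:
            violations.append(
                f"item {item.id!r}: {answer!r} not in levels {item.levels}")
        elif item.kind == "multiselect":
            bad = [a for a in answer if a not in item.options]
            if bad:
                violations.append(
                    f"item {item.id!r}: {bad} not in options {item.options}")
    return violations


# ---------------------------------------------------------------------------
# Text serialization
# ---------------------------------------------------------------------------

_ESCAPES = {"\\": "\\\\", "\n": "\\n", "\r": "\\r"}


def _escape(text: str) -> str:
    for raw, esc in _ESCAPES.items():
        text = text.replace(raw, esc)
    return text


def _unescape(text: str) -> str:
    out, i = [], 0
    while i < len(text):
        if text[i] == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"\\": "\\", "n": "\n", "r": "\r"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(text[i])
            i += 1
    return "".join(out)


def serialize_response(response: QuestionnaireResponse) -> str:
    """Human-readable key-value text; ``parse_response`` inverts it exactly."""
    lines = [
        "# mriqa questionnaire response",
        f"schema: {_escape(response.schema_id)}",
        f"series: {_escape(response.series_id)}",
        f"timestamp: {_escape(response.timestamp)}",
    ]
    for item_id, answer in response.answers.items():
        if isinstance(answer, (list, tuple)):
            value = "; ".join(_escape(a) for a in answer)
            lines.append(f"answer[{item_id}]*: {value}")
        else:
            lines.append(f"answer[{item_id}]: {_escape(str(answer))}")
    lines.append(f"comment: {_escape(response.comment)}")
    return "\n".join(lines) + "\n"


class QuestionnaireParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def parse_response(text: str) -> QuestionnaireResponse:
    """Parse the text emitted by :func:`serialize_response`."""
    fields_found: dict[str, str] = {}
    answers: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ": " not in line and not line.endswith(":"):
            raise QuestionnaireParseError(f"expected 'key: value', got {raw!r}",
                                          lineno)
        key, _, value = line.partition(":")
        key, value = key.strip(), value.lstrip(" ")
        if key.startswith("answer[") :
            if key.endswith("]*"):
                item_id = key[len("answer["):-2]
                answers[item_id] = [_unescape(v) for v in value.split("; ")] \
                    if value else []
            elif key.endswith("]"):
                item_id = key[len("answer["):-1]
                answers[item_id] = _unescape(value)
            else:
                raise QuestionnaireParseError(f"malformed answer key {key!r}",
                                              lineno)
        elif key in ("schema", "series", "timestamp", "comment"):
            fields_found[key] = _unescape(value)
        else:
            raise QuestionnaireParseError(f"unknown key {key!r}", lineno)
    if "schema" not in fields_found or "comment" not in fields_found:
        raise QuestionnaireParseError("truncated response: missing schema "
                                      "or comment field", 0)
    return QuestionnaireResponse(
        schema_id=fields_found["schema"],
        series_id=fields_found.get("series", ""),
        timestamp=fields_found.get("timestamp", ""),
        answers=answers,
        comment=fields_found["comment"],
    )


# ---------------------------------------------------------------------------
# Schema files and templates
# ---------------------------------------------------------------------------

def save_schema(schema: QuestionnaireSchema, path: str | Path) -> None:
    raw = {"id": schema.id, "items": [asdict(it) for it in schema.items]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(raw, fh, indent=2)


def load_schema(path: str | Path) -> QuestionnaireSchema:
    """Read a declarative JSON schema file."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    items = tuple(
        QuestionnaireItem(
            id=it["id"], prompt=it["prompt"], kind=it["kind"],
            levels=tuple(it.get("levels", ())),
            options=tuple(it.get("options", ())),
            show_if=tuple(it["show_if"]) if it.get("show_if") else None,
        )
        for it in raw["items"]
    )
    return QuestionnaireSchema(id=raw["id"], items=items)


def blank_response_template(schema: QuestionnaireSchema) -> str:
    """A fillable response file with prompts as comments."""
    lines = ["# mriqa questionnaire response", f"schema: {schema.id}",
             "series: ", "timestamp: "]
    for item in schema.items:
        if item.kind == "text":
            continue
        domain = item.levels if item.kind == "ordinal" else item.options
        lines.append(f"# {item.prompt} ({' | '.join(domain)})")
        suffix = "*" if item.kind == "multiselect" else ""
        lines.append(f"answer[{item.id}]{suffix}: ")
    lines.append("comment: ")
    return "\n".join(lines) + "\n"
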