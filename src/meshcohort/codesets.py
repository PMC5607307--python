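"""Named ICD-10 / OPCS-4 code sets with normalised, prefix-aware matching.

Hospital episode extracts store clinical codes without dots ("M533", "T831");
published code lists usually print them dotted ("M53.3", "T83.1").  Everything
downstream of this module works on the normalised dotless form.

Three-character codes denote whole classification sections (e.g. ICD-10 T83,
"complications of genitourinary prosthetic devices") and match any code in the
section; four-character codes are specific subcategories and match exactly.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

ICD10 = "ICD-10"
OPCS4 = "OPCS-4"
SCHEMES = (ICD10, OPCS4)

#: sets every downstream stage relies on; load_codesets refuses a config
#: that lacks any of them.
REQUIRED_SETS = (
    "mesh_insertion",
    "pop_surgery",
    "mesh_removal",
    "mesh_repair",
    "mesh_renewal",
    "incontinence_diagnosis",
    "implied_incontinence",
    "confounder_procedures",
    "benign_concomitant",
    "rescue_procedures",
    "endoscopy",
    "catheterisation",
    "periproc_complication",
    "thirty_day_complication",
    "complication_qualifiers",
    "longterm_complication",
    "longterm_qualifiers",
)

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]?$")


class CodeFormatError(ValueError):
    """Raised for clinical codes that cannot be normalised."""


class CodesetConfigError(ValueError):
    """Raised for invalid or incomplete code-set configuration."""


@dataclass(frozen=True)
class ClinicalCode:
    """A single normalised classification code."""

    scheme: str
    value: str

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise CodeFormatError(f"unknown scheme {self.scheme!r}")
        if not _CODE_RE.match(self.value):
            raise CodeFormatError(
                f"malformed {self.scheme} code {self.value!r}: expected "
                "letter + 2 digits + optional 4th character"
            )


def normalize_code(raw: str, scheme: str) -> ClinicalCode:
    """Normalise a raw code: uppercase, strip dots/whitespace, keep the
    leading <=4 significant characters.

    >>> normalize_code("M53.3", OPCS4).value
    'M533'
    """
    if raw is None:
        raise CodeFormatError("empty code")
    cleaned = re.sub(r"[\s.]", "", str(raw)).upper()
    if not cleaned:
        raise CodeFormatError("empty code")
    if len(cleaned) > 5:
        raise CodeFormatError(f"malformed code {raw!r}: too long")
    cleaned = cleaned[:4]
    return ClinicalCode(scheme, cleaned)


@dataclass
class CodeSet:
    """A named set of codes with a matching mode.

    match_mode:
      ``exact``  — a code matches only if equal to a member;
      ``prefix`` — a code matches if it begins with a member;
      ``auto``   — per-member: 3-character members act as section prefixes,
                   4-character members match exactly.

    ``attribution`` optionally maps member values to an attribution subclass
    (used by the peri-procedural complication set).
    """

    name: str
    scheme: str
    members: tuple[str, ...]
    match_mode: str = "auto"
    attribution: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.match_mode not in ("exact", "prefix", "auto"):
            raise CodesetConfigError(
                f"{self.name}: bad match_mode {self.match_mode!r}"
            )
        if not self.members:
            raise CodesetConfigError(f"code set {self.name!r} is empty")
        for m in self.members:
            ClinicalCode(self.scheme, m)  # validates
        unknown = set(self.attribution) - set(self.members)
        if unknown:
            raise CodesetConfigError(
                f"{self.name}: attribution for non-members {sorted(unknown)}"
            )

    def matches(self, code: ClinicalCode) -> bool:
        """True iff *code* belongs to this set under the set's match mode."""
        if code.scheme != self.scheme:
            raise CodesetConfigError(
                f"scheme mismatch: code is {code.scheme}, "
                f"set {self.name!r} is {self.scheme}"
            )
        return self.matches_value(code.value)

    def matches_value(self, value: str) -> bool:
        """Scheme-unchecked matching on a normalised code string."""
        for m in self.members:
            if self.match_mode == "exact":
                if value == m:
                    return True
            elif self.match_mode == "prefix":
                if value.startswith(m):
                    return True
            else:  # auto
                if len(m) == 3:
                    if value.startswith(m):
                        return True
                elif value == m:
                    return True
        return False

    def attribution_for(self, value: str) -> str | None:
        """Attribution subclass of the member matching *value*, if any."""
        for m, cls in self.attribution.items():
            if value == m or (len(m) == 3 and value.startswith(m)):
                return cls
        return None


class CodeRegistry:
    """Registry of named CodeSets loaded from one YAML configuration."""

    def __init__(self, sets: dict[str, CodeSet]):
        self._sets = dict(sets)

    def __getitem__(self, name: str) -> CodeSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def names(self) -> list[str]:
        return sorted(self._sets)

    def matches(self, name: str, value: str) -> bool:
        return self._sets[name].matches_value(value)

    def to_config(self) -> dict:
        """Canonical plain-dict form (round-trips through load_codesets)."""
        out: dict = {}
        for name in sorted(self._sets):
            s = self._sets[name]
            entry: dict = {
                "scheme": s.scheme,
                "match_mode": s.match_mode,
                "codes": list(s.members),
            }
            if s.attribution:
                entry["attribution"] = dict(s.attribution)
            out[name] = entry
        return out

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=True))

    def to_csv(self) -> str:
        """Audit export: one row per (set, member)."""
        buf = io.StringIO()
        buf.write("set,scheme,match_mode,code,attribution\n")
        for name in sorted(self._sets):
            s = self._sets[name]
            for m in s.members:
                buf.write(
                    f"{name},{s.scheme},{s.match_mode},{m},"
                    f"{s.attribution.get(m, '')}\n"
                )
        return buf.getvalue()


def default_config_path() -> Path:
    return Path(str(resources.files("meshcohort").joinpath("data/codesets.yaml")))


def load_codesets(config_path: str | Path | None = None) -> CodeRegistry:
    """Load the code-set registry from YAML (the shipped default if None).

    Raises CodesetConfigError listing any missing required set names.
    """
    path = Path(config_path) if config_path else default_config_path()
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise CodesetConfigError(f"{path}: top level must be a mapping")
    sets: dict[str, CodeSet] = {}
    for name, entry in raw.items():
        if name in sets:  # pragma: no cover - yaml keys are unique by parse
            raise CodesetConfigError(f"duplicate set name {name!r}")
        if isinstance(entry, list):
            entry = {"codes": entry}
        scheme = entry.get("scheme", ICD10)
        members = tuple(
            normalize_code(c, scheme).value for c in entry.get("codes", [])
        )
        if len(set(members)) != len(members):
            raise CodesetConfigError(f"{name}: duplicate member codes")
        attribution = {
            normalize_code(k, scheme).value: v
            for k, v in (entry.get("attribution") or {}).items()
        }
        sets[name] = CodeSet(
            name=name,
            scheme=scheme,
            members=members,
            match_mode=entry.get("match_mode", "auto"),
            attribution=attribution,
        )
    missing = [n for n in REQUIRED_SETS if n not in sets]
    if missing:
        raise CodesetConfigError(
            f"configuration is missing required code sets: {missing}"
        )
    return CodeRegistry(sets)
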