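"""Drug-name normalization via a deterministic synonym dictionary.

Spontaneous reports record drugs as trade names, salts, abbreviations,
dose-qualified strings and misspellings.  This module maps the verbatim
``prod_ai``/``drugname`` strings onto canonical single-ingredient generic
names through a curated synonym dictionary.  The interface (verbatim string
-> list of generic ingredients) is the same one an NLP concept mapper would
expose, so a dictionary produced by any such tool can be dropped in.

Lookup is deterministic and never guesses: a string whose key is absent
from the dictionary is reported as unmatched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

MATCHED = "matched"
MULTI_INGREDIENT = "multi_ingredient"
UNMATCHED = "unmatched"

#: single trailing salt/ester token stripped from a name key
DEFAULT_SALT_SUFFIXES = (
    "HYDROCHLORIDE", "DIHYDROCHLORIDE", "HCL", "MALATE", "MALEATE",
    "DIMALEATE", "MESYLATE", "TOSYLATE", "BESYLATE", "CAMSYLATE", "FUMARATE",
    "TARTRATE", "CITRATE", "PHOSPHATE", "SULFATE", "SULPHATE", "ACETATE",
    "SODIUM", "DISODIUM", "POTASSIUM", "CALCIUM", "BROMIDE",
)

#: packaging / dose-form / unit tokens removed from keys
DEFAULT_STOPWORDS = (
    "TABLET", "TABLETS", "TAB", "TABS", "CAPSULE", "CAPSULES", "CAP", "CAPS",
    "INJECTION", "INJ", "SOLUTION", "SUSPENSION", "CONCENTRATE", "INFUSION",
    "INTRAVENOUS", "IV", "ORAL", "FILM", "COATED", "EXTENDED", "RELEASE",
    "ER", "XR", "SR", "MG", "ML", "MCG", "UG", "G", "KG", "VIAL", "DOSE",
    "UNKNOWN", "NOS",
)

_DOSE_TOKEN = re.compile(r"^\d+(\.\d+)?[A-Z/%]*$")
_SEPARATORS = re.compile(r"[/\\;+]|\s+AND\s+|\s+WITH\s+")
_PUNCT = re.compile(r"[^A-Z0-9\s]")


class DictionaryConflictError(ValueError):
    """One synonym key maps to two different canonical forms."""


@dataclass
class SynonymDictionary:
    """Map from normalized name keys to canonical generic ingredient lists.

    Canonical names are lower-case and closed under the dictionary: every
    canonical name's own key maps back to itself.
    """

    entries: dict = field(default_factory=dict)
    salt_suffixes: tuple = DEFAULT_SALT_SUFFIXES
    stopwords: tuple = DEFAULT_STOPWORDS

    def add(self, synonym: str, canonicals: list[str]) -> None:
        key = normalize_key(synonym, self.salt_suffixes, self.stopwords)
        canonicals = [c.strip().lower() for c in canonicals if c.strip()]
        if not key or not canonicals:
            return
        if key in self.entries and self.entries[key] != canonicals:
            raise DictionaryConflictError(
                f"synonym key {key!r} maps to both {self.entries[key]} "
                f"and {canonicals}")
        self.entries[key] = canonicals
        # closure: canonical names resolve to themselves
        for c in canonicals:
            ckey = normalize_key(c, self.salt_suffixes, self.stopwords)
            existing = self.entries.get(ckey)
            if existing is None:
                self.entries[ckey] = [c]
            elif existing != [c] and ckey != key:
                raise DictionaryConflictError(
                    f"canonical {c!r} collides with existing entry "
                    f"{ckey!r} -> {existing}")

    def lookup(self, raw: str) -> list[str]:
        key = normalize_key(raw, self.salt_suffixes, self.stopwords)
        return list(self.entries.get(key, []))

    def __len__(self):
        return len(self.entries)


@dataclass
class NormalizationOutcome:
    raw: str
    canonical: list[str]
    status: str

    @property
    def matched(self) -> bool:
        return self.status in (MATCHED, MULTI_INGREDIENT)


def normalize_key(raw: str,
                  salt_suffixes: tuple = DEFAULT_SALT_SUFFIXES,
                  stopwords: tuple = DEFAULT_STOPWORDS) -> str:
    """Canonicalize a verbatim drug string into a dictionary key.

    Upper-cases, trims, collapses whitespace, strips punctuation, drops
    dose/stopword tokens, and strips one trailing salt suffix.
    """
    s = raw.upper().strip()
    s = _PUNCT.sub(" ", s)
    tokens = [t for t in s.split()
              if t not in stopwords and not _DOSE_TOKEN.match(t)]
    if len(tokens) > 1 and tokens[-1] in salt_suffixes:
        tokens = tokens[:-1]
    return " ".join(tokens)


def _lookup_field(raw: str, dictionary: SynonymDictionary) -> list[str]:
    canonicals: list[str] = []
    for part in _SEPARATORS.split(raw.upper()):
        if part is None or not part.strip():
            continue
        for c in dictionary.lookup(part):
            if c not in canonicals:
                canonicals.append(c)
    return canonicals


def normalize_drug(row, dictionary: SynonymDictionary) -> NormalizationOutcome:
    """Resolve one DRUG row to canonical ingredient names.

    ``prod_ai`` (already an active-ingredient field) takes precedence over
    ``drugname``; combination strings are split on ingredient separators
    before lookup.  Returns an unmatched outcome rather than guessing.
    """
    for raw in (row.prod_ai, row.drugname):
        if not raw or not raw.strip():
            continue
        canonicals = _lookup_field(raw, dictionary)
        if canonicals:
            status = MATCHED if len(canonicals) == 1 else MULTI_INGREDIENT
            return NormalizationOutcome(raw=raw, canonical=canonicals,
                                        status=status)
    return NormalizationOutcome(raw=row.prod_ai or row.drugname,
                                canonical=[], status=UNMATCHED)


def load_dictionary(path) -> SynonymDictionary:
    """Load a synonym dictionary from TSV (synonym<TAB>canonical).

    Multiple canonical ingredients of a combination product are
    '|'-separated in the canonical column.  Conflicting duplicate keys
    raise :class:`DictionaryConflictError`.
    """
    d = SynonymDictionary()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 TSV columns")
            synonym, canonical = parts
            d.add(synonym, canonical.split("|"))
    return d


def default_dictionary() -> SynonymDictionary:
    """The shipped starter dictionary (novel antineoplastic agents and
    common trade names)."""
    ref = resources.files("pvsignals.data") / "drug_synonyms.tsv"
    with resources.as_file(ref) as p:
        return load_dictionary(Path(p))
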