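"""Parameter set, functional forms and piece domains of the partitioning model.

The model describes the fraction of total main-stem leaf biomass carried
by a leaf as a function of its normalized rank (nLR, rank divided by
total leaf number, in (0, 1]).  Each developmental fine stage has a
piecewise curve built from one or two pieces, each piece being one of
four elementary forms:

========  =====================  ==============================
form      y(x)                   coefficient order
========  =====================  ==============================
linear        a·x + b            (slope, intercept)
quadratic     a·x² + b·x + c     (a, b, c)
logarithmic   a·ln(x) + b        (a, intercept)
power         a·x^b              (scale, exponent)
========  =====================  ==============================

A separate logarithmic curve (coefficients ``Llr1``, ``Llr2``) gives the
trend of normalized leaf rank against normalized development time.

The shipped default parameter file (``data/default_params.yaml``) holds
the published estimates to their three printed decimals together with
the per-stage rank intervals.  Interval conventions: interior
breakpoints belong to the upper piece, so pieces are half-open
``[lo, hi)`` except the last piece of a stage, which is closed above;
stage lower bounds keep their printed openness.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

from .errors import DomainError
from .stages import FineStage


class Form(str, Enum):
    LINEAR = "linear"
    QUADRATIC = "quadratic"
    LOGARITHMIC = "logarithmic"
    POWER = "power"


#: Number of coefficients of each elementary form.
N_COEFFS: dict[Form, int] = {
    Form.LINEAR: 2,
    Form.QUADRATIC: 3,
    Form.LOGARITHMIC: 2,
    Form.POWER: 2,
}

_INTERVAL_RE = re.compile(
    r"^\s*([\[(])\s*([^,\s]+)\s*,\s*([^,\s\])]+)\s*([\])])\s*$"
)


@dataclass(frozen=True)
class Interval:
    """A numeric interval with explicit open/closed endpoints."""

    lo: float
    hi: float
    lo_open: bool = True
    hi_open: bool = True

    def __post_init__(self):
        if not self.lo < self.hi:
            raise DomainError(f"empty interval: lo={self.lo}, hi={self.hi}")

    @classmethod
    def parse(cls, text: str) -> "Interval":
        """Parse standard bracket notation, e.g. ``"(0.10, 0.24]"``."""
        m = _INTERVAL_RE.match(text)
        if m is None:
            raise DomainError(f"cannot parse interval {text!r}")
        lb, lo, hi, rb = m.groups()
        try:
            lo_f, hi_f = float(lo), float(hi)
        except ValueError:
            raise DomainError(f"cannot parse interval {text!r}") from None
        return cls(lo_f, hi_f, lo_open=(lb == "("), hi_open=(rb == ")"))

    def contains(self, x):
        """Membership test; works element-wise on numpy arrays."""
        x = np.asarray(x)
        above = x > self.lo if self.lo_open else x >= self.lo
        below = x < self.hi if self.hi_open else x <= self.hi
        result = above & below
        return bool(result) if result.ndim == 0 else result

    def __str__(self) -> str:
        lb = "(" if self.lo_open else "["
        rb = ")" if self.hi_open else "]"
        return f"{lb}{self.lo:g}, {self.hi:g}{rb}"


def evaluate_form(form: Form, x, coeffs) -> np.ndarray:
    """Evaluate an elementary form at ``x`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(coeffs, dtype=float)
    if c.size != N_COEFFS[form]:
        raise DomainError(
            f"{form.value} form takes {N_COEFFS[form]} coefficients, got {c.size}"
        )
    if form is Form.LINEAR:
        return c[0] * x + c[1]
    if form is Form.QUADRATIC:
        return c[0] * x * x + c[1] * x + c[2]
    if form is Form.LOGARITHMIC:
        if np.any(x <= 0):
            raise DomainError("logarithmic form requires x > 0")
        return c[0] * np.log(x) + c[1]
    if form is Form.POWER:
        if np.any(x <= 0):
            raise DomainError("power form requires x > 0")
        return c[0] * np.power(x, c[1])
    raise DomainError(f"unknown form {form!r}")  # pragma: no cover


@dataclass(frozen=True)
class PieceSpec:
    """One piece of a stage curve: form, named coefficients and rank domain."""

    stage: FineStage | None
    form: Form
    coeff_names: tuple[str, ...]
    domain: Interval

    def __post_init__(self):
        if len(self.coeff_names) != N_COEFFS[self.form]:
            raise DomainError(
                f"{self.form.value} piece needs {N_COEFFS[self.form]} coefficient "
                f"names, got {self.coeff_names}"
            )
        if self.stage is not None:
            if self.domain.lo < 0.0 or self.domain.hi > 1.0:
                raise DomainError(
                    f"stage piece domain must lie within (0, 1], got {self.domain}"
                )

    def evaluate(self, x, coefficients: Mapping[str, float]) -> np.ndarray:
        values = [coefficients[name] for name in self.coeff_names]
        return evaluate_form(self.form, x, values)


def _check_ordered(stage: FineStage, pieces: Iterable[PieceSpec]) -> tuple[PieceSpec, ...]:
    pieces = tuple(pieces)
    for a, b in zip(pieces, pieces[1:]):
        if a.domain.hi > b.domain.lo:
            raise DomainError(
                f"{stage.value}: piece domains overlap ({a.domain} vs {b.domain})"
            )
        if a.domain.hi == b.domain.lo and not (a.domain.hi_open or b.domain.lo_open):
            raise DomainError(
                f"{stage.value}: breakpoint {a.domain.hi} claimed by both pieces"
            )
    return pieces


@dataclass(frozen=True)
class PartitionParams:
    """The complete named parameter set of the partitioning model.

    ``coefficients`` maps every coefficient name (``Llr1`` ... ``Lm2``)
    to its value; ``nlr_piece`` is the rank-trend curve over nDPD and
    ``stage_pieces`` the per-stage piecewise curves over nLR.
    """

    coefficients: Mapping[str, float]
    nlr_piece: PieceSpec
    stage_pieces: Mapping[FineStage, tuple[PieceSpec, ...]]

    def __post_init__(self):
        referenced: set[str] = set(self.nlr_piece.coeff_names)
        for stage, pieces in self.stage_pieces.items():
            _check_ordered(stage, pieces)
            for piece in pieces:
                referenced.update(piece.coeff_names)
        provided = set(self.coefficients)
        missing = referenced - provided
        extra = provided - referenced
        if missing:
            raise DomainError(f"missing coefficient values: {sorted(missing)}")
        if extra:
            raise DomainError(f"unreferenced coefficient values: {sorted(extra)}")

    # -- access ---------------------------------------------------------

    def coeffs_for(self, piece: PieceSpec) -> np.ndarray:
        return np.array([self.coefficients[n] for n in piece.coeff_names])

    def pieces_of(self, stage: FineStage | str) -> tuple[PieceSpec, ...]:
        return self.stage_pieces[FineStage(stage)]

    def with_coefficients(self, updates: Mapping[str, float]) -> "PartitionParams":
        """Return a copy with some coefficient values replaced."""
        unknown = set(updates) - set(self.coefficients)
        if unknown:
            raise DomainError(f"unknown coefficients: {sorted(unknown)}")
        merged = {**self.coefficients, **updates}
        return PartitionParams(merged, self.nlr_piece, self.stage_pieces)

    # -- construction / serialization -----------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "PartitionParams":
        try:
            nlr = data["nlr_model"]
            stages_block = data["stages"]
        except (KeyError, TypeError) as exc:
            raise DomainError(f"malformed parameter mapping: {exc}") from None
        coefficients: dict[str, float] = dict(nlr["coefficients"])
        nlr_piece = PieceSpec(
            stage=None,
            form=Form(nlr["form"]),
            coeff_names=tuple(nlr["coefficients"]),
            domain=Interval.parse(nlr.get("domain", "(0, 1]")),
        )
        stage_pieces: dict[FineStage, tuple[PieceSpec, ...]] = {}
        for stage_name, pieces_data in stages_block.items():
            stage = FineStage(stage_name)
            pieces = []
            for pd_ in pieces_data:
                names = tuple(pd_["coefficients"])
                coefficients.update(pd_["coefficients"])
                pieces.append(
                    PieceSpec(
                        stage=stage,
                        form=Form(pd_["form"]),
                        coeff_names=names,
                        domain=Interval.parse(pd_["domain"]),
                    )
                )
            stage_pieces[stage] = tuple(pieces)
        return cls(coefficients, nlr_piece, stage_pieces)

    def to_dict(self) -> dict:
        def piece_block(piece: PieceSpec) -> dict:
            return {
                "form": piece.form.value,
                "domain": str(piece.domain),
                "coefficients": {
                    n: float(self.coefficients[n]) for n in piece.coeff_names
                },
            }

        return {
            "nlr_model": piece_block(self.nlr_piece),
            "stages": {
                stage.value: [piece_block(p) for p in pieces]
                for stage, pieces in self.stage_pieces.items()
            },
        }

    @classmethod
    def from_yaml(cls, path) -> "PartitionParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    @functools.cache
    def default(cls) -> "PartitionParams":
        """The shipped published parameter set."""
        text = (
            resources.files("leafpart").joinpath("data/default_params.yaml").read_text()
        )
        return cls.from_dict(yaml.safe_load(text))


def default_params() -> PartitionParams:
    """Convenience alias for :meth:`PartitionParams.default`."""
    return PartitionParams.default()
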