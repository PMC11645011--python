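"""Embedded-source export of a boosted-tree model, with a verifying interpreter.

For deployment on a flash-budgeted microcontroller the trained ensemble is
transpiled into a single dependency-free C translation unit: one pure
function of the three features built only from literals, comparisons and
nested conditional expressions — the minimal dialect any embedded toolchain
accepts.  Each tree becomes one nested conditional; the function returns the
base score plus the sum of the tree expressions.  Node convention:
``feature < threshold`` takes the left branch, ties go right.

No compiler is involved anywhere: the module carries its own tokenizer,
recursive-descent parser and evaluator for the emitted dialect, so the
exported text can be verified against the native model and executed at
reduced (32-bit) precision to emulate the microcontroller's arithmetic.
In ``single`` mode thresholds and leaf values are rounded to float32 at
emission and the interpreter performs float32 comparisons and accumulation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .errors import ParseError, ScalebpError
from .model import FEATURE_COLUMNS, GBTModel


def _literal(v: float, precision: str) -> str:
    if precision == "single":
        return repr(float(np.float32(v)))
    return repr(float(v))


def _emit_node(node: dict, precision: str) -> str:
    if "value" in node:
        return _literal(node["value"], precision)
    return ("(f{f} < {t} ? {l} : {r})".format(
        f=node["feature"],
        t=_literal(node["threshold"], precision),
        l=_emit_node(node["left"], precision),
        r=_emit_node(node["right"], precision),
    ))


@dataclass
class ExportedModel:
    """One emitted translation unit plus its provenance."""

    source_text: str
    node_count: int
    emitted_bytes: int
    precision: str
    n_features: int = 3


def export_embedded_source(model: GBTModel, precision: str = "double") -> ExportedModel:
    """Transpile a model into the embedded conditional-expression dialect.

    Emission is deterministic: the same model and precision yield
    byte-identical text.
    """
    if precision not in ("double", "single"):
        raise ScalebpError(f"unknown precision {precision!r}")
    args = ", ".join(f"double f{i}" for i in range(model.n_features))
    parts = [_literal(model.base_score, precision)]
    parts += [_emit_node(t, precision) for t in model.trees]
    body = "\n        + ".join(parts)
    src = (f"double predict_{model.target}({args}) {{\n"
           f"    return {body};\n"
           f"}}\n")
    return ExportedModel(source_text=src, node_count=model.node_count(),
                         emitted_bytes=len(src.encode()),
                         precision=precision, n_features=model.n_features)


# ---------------------------------------------------------------- interpreter

_TOKEN = re.compile(r"\s*(?:(?P<num>[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?)"
                    r"|(?P<feat>f\d+)"
                    r"|(?P<op>[()?:+<]))")


class _Parser:
    """Recursive-descent parser for the emitted dialect.

    grammar:  sum    := term ('+' term)*
              term   := NUMBER | '(' cond ')'
              cond   := FEATURE '<' NUMBER '?' sum ':' sum
    """

    def __init__(self, tokens: list[str]):
        self.toks = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self, expected: str | None = None) -> str:
        tok = self.peek()
        if tok is None or (expected is not None and tok != expected):
            raise ParseError(f"expected {expected!r}, got {tok!r} at {self.pos}")
        self.pos += 1
        return tok

    def sum(self) -> list:
        terms = [self.term()]
        while self.peek() == "+":
            self.take("+")
            terms.append(self.term())
        return ["sum", terms]

    def term(self) -> list:
        tok = self.peek()
        if tok == "(":
            self.take("(")
            node = self.cond()
            self.take(")")
            return node
        num = self.take()
        try:
            return ["lit", float(num)]
        except ValueError:
            raise ParseError(f"expected a literal, got {num!r}") from None

    def cond(self) -> list:
        feat = self.take()
        if not re.fullmatch(r"f\d+", feat):
            raise ParseError(f"expected a feature, got {feat!r}")
        self.take("<")
        thr = float(self.take())
        self.take("?")
        left = self.sum()
        self.take(":")
        right = self.sum()
        return ["cond", int(feat[1:]), thr, left, right]


def parse_exported(exported: ExportedModel) -> list:
    """Parse the emitted source into an evaluable AST (raises on emitter bugs)."""
    m = re.search(r"return\s+(.*);\s*}\s*$", exported.source_text, re.DOTALL)
    if not m:
        raise ParseError("no return expression found in exported source")
    tokens = []
    pos, text = 0, m.group(1)
    while pos < len(text):
        tm = _TOKEN.match(text, pos)
        if not tm:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {text[pos]!r} at {pos}")
        tokens.append(tm.group(tm.lastgroup))
        pos = tm.end()
    parser = _Parser(tokens)
    ast = parser.sum()
    if parser.peek() is not None:
        raise ParseError(f"trailing tokens after expression: {parser.peek()!r}")
    return ast


def _eval_ast(node: list, X: np.ndarray, dtype) -> np.ndarray:
    kind = node[0]
    if kind == "lit":
        return np.full(len(X), dtype(node[1]), dtype=dtype)
    if kind == "sum":
        out = np.zeros(len(X), dtype=dtype)
        for term in node[1]:
            out = (out + _eval_ast(term, X, dtype)).astype(dtype)
        return out
    if kind == "cond":
        _, feat, thr, left, right = node
        mask = X[:, feat].astype(dtype) < dtype(thr)
        out = np.empty(len(X), dtype=dtype)
        if mask.any():
            out[mask] = _eval_ast(left, X[mask], dtype)
        if (~mask).any():
            out[~mask] = _eval_ast(right, X[~mask], dtype)
        return out
    raise ParseError(f"unknown AST node {kind!r}")


def interpret_exported(exported: ExportedModel, features) -> float | np.ndarray:
    """Evaluate the emitted conditionals exactly as written.

    Accepts one feature vector or a matrix of rows; arithmetic runs at the
    export's precision (float64, or float32 in ``single`` mode).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != exported.n_features:
        raise ScalebpError(
            f"expected {exported.n_features} features, got {X.shape[1]}")
    dtype = np.float64 if exported.precision == "double" else np.float32
    ast = parse_exported(exported)
    out = _eval_ast(ast, X, dtype).astype(float)
    return float(out[0]) if np.asarray(features).ndim == 1 else out


def degradation_report(model: GBTModel, test_rows: pd.DataFrame) -> dict:
    """PCC/ME/MAE of the exported model at double vs single precision.

    The relative performance loss per metric quantifies what the reduced
    32-bit arithmetic of the edge device costs; with well-separated
    thresholds the loss is near zero, and it is reported as |delta| so it is
    nonnegative by construction.
    """
    ycol = {"sbp": "ref_sbp", "dbp": "ref_dbp"}[model.target]
    X = test_rows[FEATURE_COLUMNS].to_numpy()
    y = test_rows[ycol].to_numpy()
    out = {}
    for precision in ("double", "single"):
        exported = export_embedded_source(model, precision)
        pred = interpret_exported(exported, X)
        out[precision] = metrics.evaluate(y, pred).as_dict()
    dd, ss = out["double"], out["single"]
    out["loss"] = {
        "pcc": abs(dd["pcc"] - ss["pcc"]),
        "mae": abs(ss["mae"] - dd["mae"]),
        "me": abs(ss["me"] - dd["me"]),
        "pcc_relative": abs(dd["pcc"] - ss["pcc"]) / abs(dd["pcc"])
        if dd["pcc"] else float("nan"),
    }
    return out
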