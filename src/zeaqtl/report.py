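"""Run-level summary statistics and set-overlap arithmetic.

Every percentage in a summary is recomputed from its own counts so the
report is self-consistent by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def union_stats(size_a: int, size_b: int, size_intersection: int
                ) -> tuple[int, float, float]:
    """Union size by inclusion-exclusion plus the shared percentage of each set.

    Returns ``(union, pct_of_a, pct_of_b)``; percentages are rounded to
    two decimals.
    """
    if size_intersection > min(size_a, size_b) or size_intersection < 0:
        raise ValueError(
            f"intersection {size_intersection} exceeds a set size "
            f"({size_a}, {size_b})"
        )
    union = size_a + size_b - size_intersection
    pct_a = round(100.0 * size_intersection / size_a, 2) if size_a else 0.0
    pct_b = round(100.0 * size_intersection / size_b, 2) if size_b else 0.0
    return union, pct_a, pct_b


def _pct(num: int, den: int, digits: int = 1) -> float:
    return round(100.0 * num / den, digits) if den else 0.0


def summarize_run(results: dict) -> dict:
    """Assemble the human-readable run summary from stage outputs.

    ``results`` may contain any of the keys used below; a missing stage is
    reported as absent rather than failing.  All percentages derive from
    the counts present in the same summary.
    """
    s: dict = {}

    if "n_snps_raw" in results:
        s["snps"] = {
            "raw": results["n_snps_raw"],
            "post_filter": results.get("n_snps_filtered"),
        }

    for stage_key in ("eqtls_stage1", "eqtls_stage2"):
        eqtls = results.get(stage_key)
        if eqtls is None:
            s[stage_key] = "absent"
            continue
        n = len(eqtls)
        n_local = sum(1 for e in eqtls if e.locality == "local")
        n_distant = n - n_local
        cat = pd.Series([e.category for e in eqtls]).value_counts().to_dict() \
            if n else {}
        s[stage_key] = {
            "n_eqtls": n,
            "mean_length_bp": float(np.mean([e.length for e in eqtls])) if n else 0.0,
            "mean_snps": float(np.mean([e.n_snps for e in eqtls])) if n else 0.0,
            "local": n_local,
            "distant": n_distant,
            "pct_local": _pct(n_local, n),
            "pct_distant": _pct(n_distant, n),
            "category_counts": cat,
            "category_pct": {c: _pct(v, n) for c, v in cat.items()},
        }

    sharing = results.get("sharing_counts")
    if sharing is not None:
        total = int(sharing.get("total", sum(
            v for k, v in sharing.items() if k != "total")))
        s["stage_comparison"] = {
            "counts": {k: int(v) for k, v in sharing.items() if k != "total"},
            "total": total,
            "pct": {k: _pct(int(v), total)
                    for k, v in sharing.items() if k != "total"},
        }

    if "n_inverse" in results:
        inv = results["n_inverse"]
        inv_local = results.get("n_inverse_local")
        s["inverse_effects"] = {
            "n": inv,
            "n_local": inv_local,
            "pct_local": _pct(inv_local, inv) if inv_local is not None else None,
        }

    if "multi_target" in results:
        s["multi_target"] = {"n": len(results["multi_target"])}

    for key in ("n_qtt_significant", "n_gwas_genes", "n_eqtl_genes"):
        if key in results:
            s[key] = results[key]
    if "candidates" in results:
        cand = results["candidates"]
        s["candidates"] = {"n": len(cand)}
        if "in_known_qtl" in getattr(cand, "columns", []):
            k = int(cand["in_known_qtl"].sum())
            s["candidates"]["in_known_qtl"] = k
            s["candidates"]["pct_in_known_qtl"] = _pct(k, len(cand), 2)

    if "motif_reports" in results:
        s["motif_enrichment"] = [r.__dict__ for r in results["motif_reports"]]

    return s


def render_summary(summary: dict, indent: int = 0) -> str:
    """Plain-text rendering of a nested summary dict."""
    lines = []
    pad = "  " * indent
    for key, val in summary.items():
        if isinstance(val, dict):
            lines.append(f"{pad}{key}:")
            lines.append(render_summary(val, indent + 1))
        elif isinstance(val, list):
            lines.append(f"{pad}{key}:")
            for item in val:
                lines.append(f"{pad}  - {item}")
        else:
            lines.append(f"{pad}{key}: {val}")
    return "\n".join(lines)
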