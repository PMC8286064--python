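"""Family classification of irp precursors via an evidence-weighted decision list.

The five families are distinguished by structural marks described for
ambulacrarian irps: octinsulins carry an extra cysteine pair (eight cysteines,
four bridges) plus neuroendocrine KR sites; dilp7 orthologs a conserved
N-terminal F domain on a two-chain precursor; IGFs a long charged C-terminal
(D+E) extension on a single-chain precursor; GSS is the residual two-chain,
six-cysteine class; multinsulins resemble dilp7 orthologs without the F domain,
with their own extra-cysteine placement or a diagnostic gene structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import Config

__all__ = ["FeatureVector", "FamilyCall", "extract_features", "classify_family",
           "FAMILIES"]

FAMILIES = ("IGF", "GSS", "octinsulin", "dilp7", "multinsulin")


@dataclass(frozen=True)
class FeatureVector:
    """Deterministic aggregation of all upstream annotations; no thresholds."""

    n_core_cys: int = 6
    n_extra_cys: int = 0
    extra_cys_domains: tuple[str, ...] = ()
    chain_mode: str = "single_chain"
    f_len: int = 0
    f_identity: float | None = None
    tail_len: int = 0
    charged_fraction: float = 0.0
    n_accepted_kr_sites: int = 0
    b_len: int = 0
    gene_signature: str | None = None
    framework_absent: bool = False
    unpaired_cys_warning: bool = False


@dataclass(frozen=True)
class FamilyCall:
    label: str
    confidence: str                       # high | medium | low
    evidence: tuple[str, ...] = ()
    runner_up: str | None = None


def extract_features(precursor, framework, annotation, tail, f_metrics, sites,
                     gene_signature: str | None = None) -> FeatureVector:
    """Aggregate upstream module outputs into a feature vector.

    A missing framework yields a flagged vector rather than an error, so that
    batch runs never abort on a single record.
    """
    if framework is None:
        return FeatureVector(n_core_cys=0, framework_absent=True,
                             gene_signature=gene_signature)
    f_len, f_identity = f_metrics if f_metrics is not None else (0, None)
    n_extra = len(framework.extra_cys)
    return FeatureVector(
        n_core_cys=6,
        n_extra_cys=n_extra,
        extra_cys_domains=tuple(tag for _i, tag in framework.extra_cys),
        chain_mode=annotation.chain_mode,
        f_len=f_len,
        f_identity=f_identity,
        tail_len=tail.tail_len,
        charged_fraction=tail.charged_fraction,
        n_accepted_kr_sites=sum(
            1 for s in sites if s.accepted and s.kind == "dibasic"),
        b_len=annotation.length("B"),
        gene_signature=gene_signature,
        unpaired_cys_warning=bool(n_extra % 2),
    )


def _domain_multiset_contains(domains: tuple[str, ...], required: list[str]) -> bool:
    pool = list(domains)
    for tag in required:
        if tag in pool:
            pool.remove(tag)
        else:
            return False
    return True


def classify_family(fv: FeatureVector, config: Config | None = None) -> FamilyCall:
    """Assign a family label; a pure function of the feature vector.

    Rules fire in order of structural specificity (extra-cysteine placement,
    F domain, charged tail, residual two-chain classes); the GSS/multinsulin
    tie is broken by the gene-structure signature when available.
    """
    cfg = config or Config()
    if fv.framework_absent:
        return FamilyCall("unclassified", "low", ("no-cysteine-framework",))

    f_min = cfg["domains.f_min"]
    oct_placement = [t.strip() for t in
                     cfg["classify.octinsulin_extra_domains"].split(",")]
    multi_domain = cfg["classify.multinsulin_extra_domain"]
    two_chain = fv.chain_mode == "two_chain"

    anomalies: list[str] = []
    if fv.unpaired_cys_warning:
        anomalies.append("unpaired-extra-cysteine")
    if fv.b_len > cfg["classify.b_max"]:
        anomalies.append("long-B-domain")

    def call(label: str, evidence: list[str], runner_up: str | None = None,
             force_low: bool = False) -> FamilyCall:
        if force_low:
            conf = "low"
        elif len(evidence) >= 2 and not anomalies:
            conf = "high"
        else:
            conf = "medium"
        return FamilyCall(label, conf, tuple(evidence + anomalies), runner_up)

    # (1) octinsulin: extra cysteine pair at the octinsulin placement + KR sites
    if (fv.n_extra_cys >= 2
            and _domain_multiset_contains(fv.extra_cys_domains, oct_placement)
            and fv.n_accepted_kr_sites >= 1):
        ev = ["extra-cys-pair@" + "+".join(oct_placement), "kr-sites"]
        if fv.gene_signature == "GSS_or_octinsulin":
            ev.append("gene-signature")
        return call("octinsulin", ev)

    # (2) dilp7: conserved F domain on a two-chain precursor
    if (fv.f_len >= f_min
            and (fv.f_identity is None
                 or fv.f_identity >= cfg["classify.f_identity_min"])
            and two_chain):
        ev = ["f-domain"]
        if fv.f_identity is not None:
            ev.append("f-identity")
        ev.append("two-chain")
        if fv.gene_signature == "dilp7":
            ev.append("gene-signature")
        return call("dilp7", ev)

    # (3) IGF: long charged tail, single chain
    if (fv.tail_len >= cfg["classify.tail_min"]
            and fv.charged_fraction >= cfg["classify.charged_min"]
            and fv.chain_mode == "single_chain"):
        ev = ["charged-tail", "single-chain"]
        if fv.gene_signature == "IGF":
            ev.append("gene-signature")
        return call("IGF", ev)

    # (4) GSS residual and (5) multinsulin, arbitrated together
    gss_fires = (two_chain and fv.tail_len < cfg["classify.tail_min"]
                 and fv.f_len < f_min
                 and fv.n_extra_cys <= cfg["classify.gss_max_extra_cys"])
    multi_extras = sum(1 for t in fv.extra_cys_domains if t == multi_domain)
    multi_fires = (two_chain and fv.f_len < f_min
                   and (multi_extras >= 2 or fv.gene_signature == "multinsulin"))
    if gss_fires and multi_fires:
        if fv.gene_signature == "multinsulin":
            return call("multinsulin", ["gene-signature", "two-chain", "no-f-domain"])
        if fv.gene_signature == "GSS_or_octinsulin":
            return call("GSS", ["gene-signature", "two-chain", "no-f-domain"])
        return call("GSS", ["two-chain", "no-f-domain"],
                    runner_up="multinsulin", force_low=True)
    if multi_fires:
        ev = []
        if multi_extras >= 2:
            ev.append(f"extra-cys-pair@{multi_domain}")
        if fv.gene_signature == "multinsulin":
            ev.append("gene-signature")
        ev += ["two-chain", "no-f-domain"]
        return call("multinsulin", ev)
    if gss_fires:
        ev = ["two-chain", "short-tail", "no-f-domain"]
        if fv.gene_signature == "GSS_or_octinsulin":
            ev.append("gene-signature")
        return call("GSS", ev)

    return FamilyCall("unclassified", "low",
                      tuple(["no-rule-fired"] + anomalies))
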