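"""Cross-study co-DEG consensus.

Three studies share two genuinely co-deregulated genes; each also reports a
study-specific gene. Only genes supported by >= 2 independent studies in the
same direction survive the consensus.
"""

from codegnet import GeneSignature, compute_codegs, support_table


def sig(study_id, up, down):
    scores = {g: 1.0 for g in up} | {g: -1.0 for g in down}
    return GeneSignature(study_id=study_id, up_genes=up, down_genes=down, scores=scores)


signatures = [
    sig("S1", up=["MYC", "KRT8", "NOISE1"], down=["FABP1"]),
    sig("S2", up=["MYC", "KRT8"], down=["FABP1", "NOISE2"]),
    sig("S3", up=["MYC", "NOISE3"], down=["NOISE4"]),
]

codegs = compute_codegs(signatures, min_support=2)
print("co-up:  ", sorted(codegs.co_up))
print("co-down:", sorted(codegs.co_down))
print()
print(support_table(codegs).to_string(index=False))
# MYC (3 studies) and KRT8/FABP1 (2 studies) pass; the NOISE genes appear in
# one study each and are filtered out, mirroring how single-study DEGs are
# discarded in a multi-study meta-analysis.
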