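"""Bundled reference tables: normalized miRNA read counts observed in
maize xylem sap under cadmium stress (three libraries: untreated 0 h c0,
untreated 1 h C1, Cd-treated 1 h Cd1).

These small compendia serve as worked-example inputs: the high-confidence
novel-miRNA table (counts, sequence, size, MFEI) and the Cd-responsive
table (C1/Cd1 counts with the reported log2 fold change and genomic
locus).  Counts are normalized reads-per-million, rounded to integers as
reported.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["high_confidence_table", "cd_response_table"]

_HIGH_CONFIDENCE_TSV = """\
mirna\tc0\tC1\tCd1\tsequence\tsize\tmfei
cme-MIR156j-p3\t27\t22\t52\tGCTCACTTCTCTTTCTGTCAGT\t22\t0.90
sof-MIR156-p3\t324\t470\t780\tGCTCACTTCTCTCTCTGTCAGC\t22\t1.00
zma-MIR166n-p3\t1179\t856\t835\tGCTGTCGTCGACCGGAGATC\t20\t1.00
zma-MIR169g-p3\t8\t6\t10\tGGCGGTCTCCTTGGCTAGCC\t20\t1.00
zma-MIR171f-p3\t30\t49\t41\tTGATTGAGCCGTGCCAATATC\t21\t0.90
sbi-MIR171h-p3\t18\t19\t10\tTTGAGCCGCGTCAATATCTC\t20\t1.10
zma-MIR397b-p5\t105\t185\t190\tTTGAGCGCAGCGTTGATGAGC\t21\t0.90
PC-5p-37430_20\t14\t16\t16\tTCTCTTAAGGCTTGTTCGGA\t20\t0.90
PC-5p-27068_30\t23\t12\t17\tACCGGAGGAGGTTAGAGGAGC\t21\t1.30
PC-5p-14301_71\t41\t76\t65\tGGTTTTAGCTTCAAGCCATCT\t21\t0.90
PC-5p-10912_100\t30\t52\t52\tCCGGAAATACCCAATATCTTG\t21\t1.00
PC-3p-7571_159\t50\t103\t60\tGGTGGCTTGTGGCTAAAACCA\t21\t0.90
PC-3p-65413_10\t4\t10\t1\tGCTTTAAGGGATCTGTTGGAGA\t22\t1.00
PC-3p-52974_13\t12\t8\t13\tAATGGTGCATTGACTTGGTC\t20\t1.10
PC-3p-49169_14\t6\t8\t16\tTTTGTCAATTTAAGAACTAAAA\t22\t1.80
PC-3p-37537_20\t88\t62\t77\tAATACTGAGCCGAATTGAAAT\t21\t1.10
PC-3p-33282_23\t11\t1\t17\tGCATCCATTCTTGGCTAAGTG\t21\t1.20
PC-3p-18761_49\t21\t46\t43\tGCCTGTATGCACTCTCGGTG\t20\t0.90
PC-3p-18578_50\t17\t22\t20\tTTTATGATATGTTACTCTACT\t21\t1.50
PC-3p-10246_108\t65\t7\t44\tCAGGCCTTCTTGGCTAAGCG\t20\t0.90
PC-3p-100706_6\t8\t8\t15\tGGAGCTGCAAACACTCTGGT\t20\t1.50
osa-MIR1430-p5\t58\t34\t63\tCTTAGCCAAGAATGGCTTGCCT\t22\t1.00
"""

_CD_RESPONSE_TSV = """\
mirna\tC1\tCd1\tlog2fc\tchrom\tstrand\tstart\tend\thairpin_len\tdirection
PC-3p-10246_108\t7\t44\t2.73\tchr3\t+\t229987606\t229987776\t167\tup
PC-3p-33282_23\t1\t17\t4.20\tchr3\t-\t96704531\t96704709\t176\tup
zma-miR169l-5p\t31\t107\t1.77\tchr1\t+\t298277019\t298277107\t87\tup
zma-miR398a-3p\t31\t73\t1.23\tchr7\t+\t38540171\t38540278\t106\tup
zma-miR398a-3p\t31\t73\t1.23\tchr2\t+\t169527758\t169527897\t138\tup
zma-miR164d-3p_R+1\t6\t1\t-2.47\tchr7\t-\t172723300\t172723515\t214\tdown
PC-3p-74571_8\t9\t4\t-1.21\tchr2\t+\t22503757\t22503904\t142\tdown
PC-5p-167816_4\t5\t1\t-2.21\tchr8\t-\t103189069\t103189246\t135\tdown
PC-5p-395659_2\t5\t1\t-2.21\tchr1\t+\t296265246\t296265464\t216\tdown
PC-5p-76360_8\t5\t1\t-2.21\tchr1\t-\t52464270\t52464417\t103\tdown
PC-3p-65413_10\t10\t1\t-3.34\tchr6\t+\t161474760\t161474953\t129\tdown
"""


def high_confidence_table() -> pd.DataFrame:
    """High-confidence novel miRNAs of maize xylem sap: per-library
    normalized counts, mature sequence, size (nt) and precursor MFEI."""
    return pd.read_csv(io.StringIO(_HIGH_CONFIDENCE_TSV), sep="\t")


def cd_response_table() -> pd.DataFrame:
    """Cd-responsive miRNAs of maize xylem sap: C1/Cd1 normalized counts,
    reported log2 fold change and the precursor's genomic locus.  One
    miRNA (zma-miR398a-3p) is reported at two loci."""
    return pd.read_csv(io.StringIO(_CD_RESPONSE_TSV), sep="\t")
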