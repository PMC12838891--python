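# ADME profiles of the four designed dual inhibitors, whose structures are
# not public. Values are the printed predictions for each compound; fields
# never printed are SYNTHETIC stand-ins chosen to be consistent with the
# printed rule outcomes: hbd/hba for ICLID(1/8), PFLID(1/9), PFL(2/8);
# sa_score for all four; single representative values where only a range or
# approximation was printed (ICLID log_s -7.80 = most favorable end of
# -7.80..-10.07; PFLID -8.50 of -8.50..-10.27; ICL log_s -5.5 for ">-6";
# PFL log_s -6.5 for "about -6..-7"; ICL mw 495 as printed despite the
# inconsistent "-135 g/mol" delta; PFL mw 520, logp_max 5.5 nominal).
compound,mw,logp_consensus,logp_max_method,log_s,ba_score,hbd,hba,lipinski_violations,ghose_violations,muegge_violations,alerts,gi_absorption,sa_score
ICLID,603.66,4.53,6.72,-7.80,0.55,1,8,1,2,1,michael_acceptor;quaternary_nitrogen;stilbene,low,6.0
PFLID,629.73,5.23,8.61,-8.50,0.17,1,9,2,4,3,quaternary_nitrogen,low,6.5
ICL,495.0,3.2,4.5,-5.5,0.55,3,7,0,1,0,,high,3.9
PFL,520.0,4.0,5.5,-6.5,0.55,2,8,1,1,0,,high,4.3
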