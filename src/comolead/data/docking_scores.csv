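compound,target,vina_kcal_mol,volume_A3
GLA,3UYS,-6.7,877
LIC,3UYS,-7.1,637
LID,3UYS,-8.0,637
MLT,3UYS,-6.8,877
GLA,5OAT,-7.1,2559
LIC,5OAT,-8.6,2559
LID,5OAT,-7.8,2559
MLT,5OAT,-6.9,2559
ICLID,3UYS,-8.5,637
IC261,3UYS,-6.5,637
ICLID,5OAT,-10.3,3727
IC261,5OAT,-7.3,2559
PFLID,3UYS,-9.8,637
PF670462,3UYS,-7.9,637
PFLID,5OAT,-10.0,3727
PF670462,5OAT,-7.8,2559
ICL,3UYS,-7.2,637
ICL,5OAT,-8.9,3727
PFL,3UYS,-10.8,651
PFL,5OAT,-11.2,3727
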