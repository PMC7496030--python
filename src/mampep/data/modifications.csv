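# Elemental deltas of the monitored modifications. position: any | nterm | cterm_chain.
# rt_offset_min is the deterministic retention-time shift used by the synthetic generator;
# rt_resolved marks species distinguishable from their parent only chromatographically.
name,targets,position,dC,dH,dN,dO,dS,rt_resolved,rt_offset_min
deamidation,N,any,0,-1,-1,1,0,0,0.5
oxidation,MW,any,0,0,0,1,0,0,-1.0
succinimide,N,any,0,-3,-1,0,0,0,0.6
succinimide,D,any,0,-2,0,-1,0,0,0.6
NH3 loss,NQR,any,0,-3,-1,0,0,0,0.3
H2O loss,DSTE,any,0,-2,0,-1,0,0,0.4
Gln->PyroGlu,Q,nterm,0,-3,-1,0,0,0,1.0
Lys loss,K,cterm_chain,-6,-12,-2,-1,0,0,-0.3
isomerisation,D,any,0,0,0,0,0,1,0.8
oxolactone,W,any,0,-2,0,1,0,0,-0.8
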