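ingredient,synonym
infliximab,infliximab
infliximab,remicade
infliximab,inflectra
infliximab,renflexis
infliximab,avsola
infliximab,ixifi
infliximab,infliximab-dyyb
infliximab,infliximab-abda
infliximab,infliximab-axxq
azathioprine,azathioprine
azathioprine,imuran
azathioprine,azasan
azathioprine,imurel
azathioprine,azamun
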