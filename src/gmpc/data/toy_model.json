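{
"metabolites":[
{
"id":"glc__D_e",
"name":"",
"compartment":"e"
},
{
"id":"no3_e",
"name":"",
"compartment":"e"
},
{
"id":"co2_e",
"name":"",
"compartment":"e"
},
{
"id":"photon_e",
"name":"",
"compartment":"e"
},
{
"id":"o2_e",
"name":"",
"compartment":"e"
},
{
"id":"glc__D_c",
"name":"",
"compartment":"c"
},
{
"id":"no3_c",
"name":"",
"compartment":"c"
},
{
"id":"co2_c",
"name":"",
"compartment":"c"
},
{
"id":"photon_c",
"name":"",
"compartment":"c"
},
{
"id":"o2_c",
"name":"",
"compartment":"c"
}
],
"reactions":[
{
"id":"EX_glc__D_e",
"name":"",
"metabolites":{
"glc__D_e":-1
},
"lower_bound":-1000.0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"EX_no3_e",
"name":"",
"metabolites":{
"no3_e":-1
},
"lower_bound":-1000.0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"EX_co2_e",
"name":"",
"metabolites":{
"co2_e":-1
},
"lower_bound":-1000.0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"EX_photon_e",
"name":"",
"metabolites":{
"photon_e":-1
},
"lower_bound":-1000.0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"EX_o2_e",
"name":"",
"metabolites":{
"o2_e":-1
},
"lower_bound":-1000.0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"GLCt",
"name":"",
"metabolites":{
"glc__D_c":1,
"glc__D_e":-1
},
"lower_bound":0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"NO3t",
"name":"",
"metabolites":{
"no3_c":1,
"no3_e":-1
},
"lower_bound":0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"CO2t",
"name":"",
"metabolites":{
"co2_c":1,
"co2_e":-1
},
"lower_bound":-1000.0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"PHOTONt",
"name":"",
"metabolites":{
"photon_c":1,
"photon_e":-1
},
"lower_bound":0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"O2t",
"name":"",
"metabolites":{
"o2_c":1,
"o2_e":-1
},
"lower_bound":-1000.0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"BIOMASS_light",
"name":"",
"metabolites":{
"co2_c":-40.0,
"no3_c":-5.208571428571428,
"o2_c":40.0,
"photon_c":-400.0
},
"lower_bound":0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"BIOMASS_dark",
"name":"",
"metabolites":{
"co2_c":127.63478260869564,
"glc__D_c":-27.93913043478261,
"no3_c":-6.160869565217391,
"o2_c":-127.63478260869564
},
"lower_bound":0,
"upper_bound":1000.0,
"gene_reaction_rule":""
}
],
"genes":[],
"id":"gmpc_toy",
"compartments":{
"c":"",
"e":""
},
"version":"1"
}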