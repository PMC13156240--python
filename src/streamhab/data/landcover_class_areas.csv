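class,area_2008_km2,area_2019_km2,area_2024_km2
Open Water,1785,1866,1850
"Developed, Open Space",6330,6476,6720
"Developed, Low Intensity",3084,3259,3365
"Developed, Medium Intensity",641,730,781
"Developed, High Intensity",156,181,195
Barren Land,347,366,480
Deciduous Forest,254,239,236
Evergreen Forest,38500,35759,35521
Mixed Forest,846,648,590
Shrub/Scrub,4270,5065,5457
Herbaceous,4830,6665,6409
Hay/Pasture,7140,7527,7826
Cultivated Crops,17730,17426,16885
Woody Wetlands,30831,30611,30025
Emergent Herbaceous Wetlands,868,794,1271
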