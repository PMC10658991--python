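[{"idx":0,"coef":[0.424470848077218,0.321297235350146,-0.0308121233031793],"se":[0.466699171465204,0.364225362994806,0.298179091091883],"loglik":-40.6585006223491},{"idx":1,"coef":0.567894002662729,"se":0.315373911376352,"loglik":-45.7820518063021},{"idx":2,"coef":0.520259067513067,"se":0.25339623864297,"loglik":-77.73497949083},{"idx":3,"coef":[-0.370150484123836,-0.639174337035121,-0.412951038122822],"se":[0.350344786947078,0.423126510630786,0.301501348333864],"loglik":-24.9758753288089},{"idx":4,"coef":[0.218807879284714,-0.169025082011501,-0.412284112425148],"se":[0.435508759587947,0.314750657549928,0.31307465611891],"loglik":-28.7970305598659},{"idx":5,"coef":[0.374295742560945,0.597706816341402,0.0540216247369175],"se":[0.508440991361867,0.440164995934494,0.284250347725218],"loglik":-36.7763200330738},{"idx":6,"coef":[0.124609828403902,-0.0223546279337357,-0.293003957566013],"se":[0.206836276944253,0.189325916856553,0.18009280692513],"loglik":-86.4420173379891},{"idx":7,"coef":[-0.0657942200518856,-0.11469163437225],"se":[0.356960818439293,0.39692259121274],"loglik":-22.6888721831783},{"idx":8,"coef":[0.0193036940386687,-0.545186315324851],"se":[0.257967186230467,0.314250588861703],"loglik":-58.1651983390874},{"idx":9,"coef":[0.00678563216412531,0.0965781609139772],"se":[0.346193466329039,0.302608154644105],"loglik":-33.3724221004841},{"idx":10,"coef":[-0.376691285746335,-0.162907254209466,0.376199981448028],"se":[0.217661499030958,0.131763710220793,0.260339607517268],"loglik":-75.5727737877719},{"idx":11,"coef":[-0.110119090215315,0.0663888963560932],"se":[0.156393261163988,0.181265671633927],"loglik":-95.7530974954174},{"idx":12,"coef":[-0.0957821093294793,0.113459583013351],"se":[0.208358624947567,0.216076270619793],"loglik":-66.1042011031339},{"idx":13,"coef":[0.0102725958646631,-0.00562137294938108,0.116781922899703],"se":[0.357970515100078,0.411466283914616,0.455661230792221],"loglik":-20.370380734408},{"idx":14,"coef":[-0.0707410808889979,0.268470208938103,-0.169075380677664],"se":[0.262957837671486,0.296228318157961,0.232234429950179],"loglik":-32.3449624201164},{"idx":15,"coef":[-0.231696903846426,-0.134988146261462],"se":[0.207375623124003,0.20943623834428],"loglik":-95.401719494194},{"idx":16,"coef":[-0.204707129389059,-0.480740517838617,-0.397334631948396],"se":[0.173468729990501,0.304793140254434,0.23756623087787],"loglik":-80.5510290074604},{"idx":17,"coef":[-0.407018318220103,-0.121292203682225,-0.655698116241262],"se":[0.28855617717267,0.209570160704714,0.270685658340364],"loglik":-52.5653834995949},{"idx":18,"coef":[-0.312187526759462,-0.140019019376023],"se":[0.29785109478104,0.277038369907822],"loglik":-33.7459629860984},{"idx":19,"coef":0.218668514599377,"se":0.171542074444323,"loglik":-102.21779467001},{"idx":20,"coef":[-0.0133163657274679,-0.489503811708168],"se":[0.221017148550206,0.25032486773837],"loglik":-65.294163718467},{"idx":21,"coef":[-0.230613851813251,-0.154990078694526,0.290283935942312],"se":[0.28492860359496,0.240852572426983,0.241353649799176],"loglik":-48.3076230540005},{"idx":22,"coef":0.404740324472916,"se":0.627077907670547,"loglik":-11.3630828201598},{"idx":23,"coef":[-0.108144835923444,0.199008577944522],"se":[0.164783317980086,0.219407843818281],"loglik":-62.4906431163664},{"idx":24,"coef":0.0525485502078883,"se":0.301299682518584,"loglik":-19.2504802343049}]
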